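"""Per-drug side-effect scoring and the two-step prediction strategy.

Guilt by association: a query drug inherits evidence for side effect C_j
from training drugs labeled with C_j, weighted by how strongly it
interacts with them.

* direct:     Pi^c(d -> C_j) = sum_{di in S'} Q^c(d, di) * c_{i,j}
* hybrid:     Pi^h(d -> C_j) = sum_{di in S'} Q^h(d, di) * c_{i,j}
* similarity: Pi^s(d -> C_j) = max_{di in S'} Q^s(d, di) * c_{i,j}

The two-step predictor tries the direct score first and falls back to the
hybrid score only when the direct vector is all-zero (the query has no
interactive training drug at all).  Any training drug with the same
identifier as the query is excluded from S'.
"""

from __future__ import annotations

import logging
from typing import Optional

from .containers import (
    InteractionTable,
    LabelMatrix,
    ProteinChemicalTable,
    RankedPrediction,
    ScoreVector,
)
from .interaction_scores import hybrid_score
from .similarity import SimilarityProvider

logger = logging.getLogger(__name__)


def score_direct(
    d: str, train: LabelMatrix, cc: InteractionTable
) -> ScoreVector:
    """Sum of direct interaction scores into each side-effect category."""
    scores = {e: 0.0 for e in train.effects}
    for di, q in cc.neighbors(d).items():
        if di == d or di not in train or q <= 0:
            continue
        for e in train.effects_of(di):
            scores[e] += q
    return ScoreVector(drug=d, scores=scores, method="direct")


def score_hybrid(
    d: str,
    train: LabelMatrix,
    cc: InteractionTable,
    pc: ProteinChemicalTable,
) -> ScoreVector:
    """Sum of shared-neighbor hybrid scores into each category."""
    scores = {e: 0.0 for e in train.effects}
    for di in train.drugs:
        if di == d:
            continue
        q = hybrid_score(d, di, cc, pc)
        if q <= 0:
            continue
        for e in train.effects_of(di):
            scores[e] += q
    return ScoreVector(drug=d, scores=scores, method="hybrid")


def score_similarity(
    d: str, train: LabelMatrix, provider: SimilarityProvider
) -> ScoreVector:
    """Maximum structural similarity to any training drug per category.

    A provider failure for a pair is treated as similarity 0 (logged), so
    one unparseable structure never aborts a prediction run.
    """
    scores = {e: 0.0 for e in train.effects}
    for di in train.drugs:
        if di == d:
            continue
        try:
            q = provider.similarity(d, di)
        except Exception as exc:  # degrade, never abort
            logger.warning("similarity(%r, %r) failed (%s); using 0", d, di, exc)
            q = 0.0
        if q <= 0:
            continue
        for e in train.effects_of(di):
            if q > scores[e]:
                scores[e] = q
    return ScoreVector(drug=d, scores=scores, method="similarity")


def rank(scores: ScoreVector, train: LabelMatrix) -> RankedPrediction:
    """Order side effects by descending score; zero scores are omitted.

    Ties break on higher training prevalence N(C_i), then on catalog
    index, so the ordering is fully deterministic.
    """
    counts = train.effect_counts()
    index = {e: i for i, e in enumerate(train.effects)}
    positive = [e for e in train.effects if scores.scores.get(e, 0.0) > 0]
    ordered = sorted(
        positive, key=lambda e: (-scores.scores[e], -counts[e], index[e])
    )
    items = [(r, e, scores.scores[e]) for r, e in enumerate(ordered, start=1)]
    return RankedPrediction(drug=scores.drug, items=items, method=scores.method)


def predict_two_step(
    d: str,
    train: LabelMatrix,
    cc: InteractionTable,
    pc: ProteinChemicalTable,
) -> RankedPrediction:
    """Direct scoring first; hybrid fallback when no direct evidence exists.

    Returns an empty prediction (hybrid-tagged) when neither route yields
    a positive score; evaluation then counts every order as a miss.
    """
    direct = score_direct(d, train, cc)
    if not direct.is_trivial():
        return rank(direct, train)
    hybrid = score_hybrid(d, train, cc, pc)
    return rank(hybrid, train)


def predict_similarity(
    d: str, train: LabelMatrix, provider: SimilarityProvider
) -> RankedPrediction:
    """Rank by the structural-similarity baseline."""
    return rank(score_similarity(d, train, provider), train)
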
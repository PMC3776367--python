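"""Jackknife and hold-out evaluation with order-wise accuracy profiles.

For each evaluated drug the ranked prediction is compared against its true
side effects order by order: P(j) counts drugs whose j-th ranked candidate
is a true effect, and AC(j) = P(j) / N where N is the number of
structure-different drugs evaluated.  N stays fixed across orders — a
drug whose prediction list is shorter than j simply misses at order j.

The jackknife removes only a drug's labels from the training matrix (by
excluding the drug from S' via identifier match inside the scorers); its
interaction-network edges and similarity scores remain available, since
the network is external knowledge rather than part of the label model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Tuple

import numpy as np

from .containers import (
    AccuracyProfile,
    InteractionTable,
    LabelMatrix,
    ProteinChemicalTable,
    RankedPrediction,
)
from .ranking import predict_similarity, predict_two_step
from .similarity import SimilarityProvider

INTERACTION = "interaction"
SIMILARITY = "similarity"


@dataclass
class DrugResult:
    """Per-drug evaluation log entry."""

    drug: str
    method_used: str
    n_predicted: int
    first_hit_order: Optional[int]


def accuracy_profile(
    predictions: Iterable[RankedPrediction],
    truth: LabelMatrix,
    m: Optional[int] = None,
) -> AccuracyProfile:
    """Order-wise accuracy of ranked predictions against a truth matrix.

    Every evaluated drug must have a truth row; ``m`` defaults to the
    truth catalog size.
    """
    preds = list(predictions)
    if m is None:
        m = truth.n_effects
    hits = np.zeros(m, dtype=int)
    n = 0
    for pred in preds:
        if pred.drug not in truth:
            raise ValueError(f"drug {pred.drug!r} has no truth labels")
        n += 1
        true_effects = truth.effects_of(pred.drug)
        for j in range(1, m + 1):
            effect = pred.effect_at(j)
            if effect is not None and effect in true_effects:
                hits[j - 1] += 1
    if n == 0:
        raise ValueError("no drugs to evaluate")
    return AccuracyProfile(hits=hits, n_drugs=n)


def _predictor(
    method: str,
    cc: Optional[InteractionTable],
    pc: Optional[ProteinChemicalTable],
    provider: Optional[SimilarityProvider],
) -> Callable[[str, LabelMatrix], RankedPrediction]:
    if method == INTERACTION:
        if cc is None or pc is None:
            raise ValueError("interaction method needs both interaction tables")
        return lambda d, train: predict_two_step(d, train, cc, pc)
    if method == SIMILARITY:
        if provider is None:
            raise ValueError("similarity method needs a similarity provider")
        return lambda d, train: predict_similarity(d, train, provider)
    raise ValueError(f"unknown method {method!r}")


def _evaluate(
    query_drugs: Iterable[str],
    train: LabelMatrix,
    truth: LabelMatrix,
    method: str,
    cc: Optional[InteractionTable],
    pc: Optional[ProteinChemicalTable],
    provider: Optional[SimilarityProvider],
    mode: str,
) -> Tuple[AccuracyProfile, List[DrugResult]]:
    predict = _predictor(method, cc, pc, provider)
    predictions: List[RankedPrediction] = []
    log: List[DrugResult] = []
    for d in query_drugs:
        pred = predict(d, train)
        predictions.append(pred)
        true_effects = truth.effects_of(d)
        first_hit = next(
            (r for r, e, _ in pred.items if e in true_effects), None
        )
        log.append(DrugResult(d, pred.method, len(pred), first_hit))
    profile = accuracy_profile(predictions, truth, m=train.n_effects)
    profile.mode = mode
    profile.method = method
    return profile, log


def jackknife_evaluate(
    train: LabelMatrix,
    method: str = INTERACTION,
    cc: Optional[InteractionTable] = None,
    pc: Optional[ProteinChemicalTable] = None,
    provider: Optional[SimilarityProvider] = None,
) -> Tuple[AccuracyProfile, List[DrugResult]]:
    """Leave-one-out evaluation over the training drugs.

    Each drug is predicted with its own labels withheld (the scorers skip
    identifier-matched training drugs, which is equivalent to zeroing its
    label row); N = number of training drugs.  Deterministic.
    """
    if train.n_drugs < 2:
        raise ValueError("jackknife needs at least 2 training drugs")
    return _evaluate(
        train.drugs, train, train, method, cc, pc, provider, mode="jackknife"
    )


def holdout_evaluate(
    train: LabelMatrix,
    test: LabelMatrix,
    method: str = INTERACTION,
    cc: Optional[InteractionTable] = None,
    pc: Optional[ProteinChemicalTable] = None,
    provider: Optional[SimilarityProvider] = None,
) -> Tuple[AccuracyProfile, List[DrugResult]]:
    """Predict each test drug against the full training matrix; N = |test|."""
    overlap = set(train.drugs) & set(test.drugs)
    if overlap:
        raise ValueError(f"train and test sets overlap: {sorted(overlap)[:5]}")
    return _evaluate(
        test.drugs, train, test, method, cc, pc, provider, mode="holdout"
    )


def no_skill_ac1(truth: LabelMatrix, m: Optional[int] = None) -> float:
    """Expected AC(1) of a uniformly random ranking: mean |true effects| / m."""
    if m is None:
        m = truth.n_effects
    return float(
        np.mean([len(truth.effects_of(d)) for d in truth.drugs]) / m
    )
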
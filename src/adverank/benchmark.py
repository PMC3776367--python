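"""Benchmark construction: top-k side-effect selection, interaction-coverage
filtering, virtual-drug accounting and the random train/test split.

A "virtual drug" counts one structural compound once per side-effect
category it belongs to, so N(vir) = sum_i N(C_i) while N(str) is the
number of distinct compounds.  Selection keeps the k side effects with
the most drugs (ties at the cutoff broken by first-seen order), then
drugs lacking both chemical-chemical and protein-chemical interactions
are excluded — a drug with either kind of neighbor survives.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, OrderedDict
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .containers import (
    BenchmarkDataset,
    InteractionTable,
    LabelMatrix,
    ProteinChemicalTable,
    SideEffectCatalog,
)

logger = logging.getLogger(__name__)


def select_top_side_effects(
    labels: Iterable[Tuple[str, str]], k: int = 100
) -> Tuple[SideEffectCatalog, LabelMatrix]:
    """Keep the ``k`` side effects with the largest drug counts.

    Label pairs outside the retained catalog are dropped, and drugs left
    without any positive label are removed.  Ties at the rank-``k`` cutoff
    are broken by first-seen order, so the result is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = list(labels)
    drug_order: "OrderedDict[str, None]" = OrderedDict()
    effect_order: "OrderedDict[str, None]" = OrderedDict()
    counts: Counter = Counter()
    seen = set()
    for d, e in pairs:
        if (d, e) in seen:
            continue
        seen.add((d, e))
        drug_order.setdefault(d, None)
        effect_order.setdefault(e, None)
        counts[e] += 1
    all_effects = list(effect_order)
    if k > len(all_effects):
        logger.warning(
            "requested top %d side effects but only %d available; keeping all",
            k,
            len(all_effects),
        )
        k = len(all_effects)
    # stable sort on descending count keeps first-seen order among ties
    ranked = sorted(all_effects, key=lambda e: -counts[e])
    kept_effects = [e for e in all_effects if e in set(ranked[:k])]
    kept_set = set(kept_effects)
    per_drug: dict = {d: set() for d in drug_order}
    for d, e in seen:
        if e in kept_set:
            per_drug[d].add(e)
    kept_drugs = [d for d in drug_order if per_drug[d]]
    matrix = LabelMatrix(kept_drugs, kept_effects, per_drug)
    catalog = matrix.to_catalog()
    return catalog, matrix


def filter_uncovered_drugs(
    labels: LabelMatrix,
    cc: InteractionTable,
    pc: ProteinChemicalTable,
) -> LabelMatrix:
    """Drop drugs that have neither a chemical nor a protein neighbor.

    A drug with at least one positive-score neighbor of either kind is
    kept.  Side effects emptied by the removal are dropped from the
    catalog (and logged) so the matrix invariants continue to hold.
    Idempotent.
    """
    kept = [
        d
        for d in labels.drugs
        if cc.neighbors(d) or pc.proteins_of(d)
    ]
    removed = labels.n_drugs - len(kept)
    if removed:
        logger.info("excluded %d drugs without any interaction coverage", removed)
    sub = labels.subset(kept)
    counts = sub.effect_counts()
    live_effects = [e for e in sub.effects if counts[e] > 0]
    if len(live_effects) < sub.n_effects:
        logger.info(
            "dropped %d side-effect categories emptied by coverage filtering",
            sub.n_effects - len(live_effects),
        )
        sub = LabelMatrix(
            sub.drugs, live_effects, {d: sub.effects_of(d) for d in sub.drugs}
        )
    return sub


def count_virtual_drugs(labels: LabelMatrix) -> Tuple[int, int]:
    """(N(str), N(vir)): distinct compounds and total positive labels."""
    n_structural = labels.n_drugs
    n_virtual = sum(labels.effect_counts().values())
    return n_structural, n_virtual


def count_single_label_drugs(labels: LabelMatrix) -> int:
    """Number of drugs carrying exactly one side effect."""
    return sum(1 for d in labels.drugs if len(labels.effects_of(d)) == 1)


def split_train_test(
    drugs: Sequence[str], fraction: float, seed: int
) -> Tuple[List[str], List[str]]:
    """Random train/test partition with |test| = half-down rounded share.

    The test size is ceil(fraction * n - 0.5): exact halves round down,
    so a 10% split of 835 drugs yields 83 test drugs.  Sampling is
    uniform without replacement and fully determined by ``seed``; both
    returned lists preserve the original drug order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(drugs)
    n_test = math.ceil(fraction * n - 0.5)
    if n_test < 1 or n_test >= n:
        raise ValueError(
            f"fraction {fraction} yields an empty split side for n={n}"
        )
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    test = [drugs[i] for i in sorted(test_idx)]
    train = [drugs[i] for i in range(n) if i not in test_idx]
    return train, test


def build_benchmark(
    label_pairs: Iterable[Tuple[str, str]],
    cc: InteractionTable,
    pc: ProteinChemicalTable,
    top_k: int = 100,
    test_fraction: float = 0.1,
    split_seed: int = 0,
) -> BenchmarkDataset:
    """Full benchmark pipeline: top-k selection, coverage filter, split."""
    _, matrix = select_top_side_effects(label_pairs, top_k)
    matrix = filter_uncovered_drugs(matrix, cc, pc)
    if matrix.n_drugs < 2:
        raise ValueError("fewer than 2 drugs survive benchmark construction")
    train, test = split_train_test(matrix.drugs, test_fraction, split_seed)
    return BenchmarkDataset(
        labels=matrix,
        catalog=matrix.to_catalog(),
        train_drugs=tuple(train),
        test_drugs=tuple(test),
        split_seed=split_seed,
    )
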
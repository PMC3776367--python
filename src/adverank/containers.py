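"""In-memory containers for interaction networks, label matrices and
prediction results.

The two interaction tables are sparse maps backed by adjacency
dictionaries: a chemical-chemical table stores a symmetric confidence
score Q^c(d1, d2) per unordered drug pair, and a protein-chemical table
stores Q^p(p, d) per (protein, drug) pair.  Absent pairs score 0 — a
missing interaction and "no evidence" are the same thing throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np


class InteractionTable:
    """Symmetric sparse map of unordered drug pairs to confidence scores.

    Only strictly positive scores are stored; ``score`` returns 0 for any
    absent pair.  Duplicate insertions of the same unordered pair keep the
    maximum score.  Self-pairs are rejected: a drug never carries evidence
    about itself through the network.
    """

    def __init__(self) -> None:
        self._adj: Dict[str, Dict[str, float]] = {}

    def add(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a!r}")
        if score < 0:
            raise ValueError(f"negative score {score} for pair ({a!r}, {b!r})")
        if score == 0:
            return
        current = self._adj.get(a, {}).get(b, 0.0)
        if score > current:
            self._adj.setdefault(a, {})[b] = score
            self._adj.setdefault(b, {})[a] = score

    def score(self, a: str, b: str) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, d: str) -> Dict[str, float]:
        """Map of drugs with positive score against ``d`` to their scores."""
        return self._adj.get(d, {})

    def drugs(self) -> List[str]:
        return list(self._adj)

    def pairs(self) -> Iterator[Tuple[str, str, float]]:
        """Each unordered pair once, (a, b, score) with a < b lexically."""
        for a, nbrs in self._adj.items():
            for b, s in nbrs.items():
                if a < b:
                    yield a, b, s

    @property
    def n_pairs(self) -> int:
        return sum(len(n) for n in self._adj.values()) // 2

    def __eq__(self, other: object) -> bool:
        return isinstance(other, InteractionTable) and self._adj == other._adj

    def __repr__(self) -> str:
        return f"InteractionTable({self.n_pairs} pairs, {len(self._adj)} drugs)"


class ProteinChemicalTable:
    """Sparse map of (protein, drug) pairs to confidence scores.

    Absent pairs score 0.  Duplicates keep the maximum.
    """

    def __init__(self) -> None:
        self._by_drug: Dict[str, Dict[str, float]] = {}

    def add(self, protein: str, chemical: str, score: float) -> None:
        if score < 0:
            raise ValueError(
                f"negative score {score} for ({protein!r}, {chemical!r})"
            )
        if score == 0:
            return
        current = self._by_drug.get(chemical, {}).get(protein, 0.0)
        if score > current:
            self._by_drug.setdefault(chemical, {})[protein] = score

    def score(self, protein: str, chemical: str) -> float:
        return self._by_drug.get(chemical, {}).get(protein, 0.0)

    def proteins_of(self, chemical: str) -> Dict[str, float]:
        """Map of proteins with positive score against the drug."""
        return self._by_drug.get(chemical, {})

    def chemicals(self) -> List[str]:
        return list(self._by_drug)

    def records(self) -> Iterator[Tuple[str, str, float]]:
        for c, prots in self._by_drug.items():
            for p, s in prots.items():
                yield p, c, s

    @property
    def n_records(self) -> int:
        return sum(len(p) for p in self._by_drug.values())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ProteinChemicalTable)
            and self._by_drug == other._by_drug
        )

    def __repr__(self) -> str:
        return f"ProteinChemicalTable({self.n_records} records)"


@dataclass(frozen=True)
class SideEffectCatalog:
    """Ordered side-effect identifiers with display names and drug counts.

    The ordering is fixed at construction and defines the catalog index
    used as the final ranking tie-break.
    """

    effects: Tuple[str, ...]
    counts: Mapping[str, int]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.effects)) != len(self.effects):
            raise ValueError("duplicate side-effect identifiers in catalog")
        for e in self.effects:
            if self.counts.get(e, 0) < 1:
                raise ValueError(f"catalog effect {e!r} has count < 1")

    def __len__(self) -> int:
        return len(self.effects)

    def index(self, effect: str) -> int:
        return self.effects.index(effect)


class LabelMatrix:
    """Binary drug x side-effect membership.

    Drugs and effects keep first-seen order.  Every drug is expected to
    carry at least one positive label and every catalog effect at least
    one drug; builders in the benchmark module enforce this.
    """

    def __init__(
        self,
        drugs: Sequence[str],
        effects: Sequence[str],
        labels: Mapping[str, Iterable[str]],
    ) -> None:
        self.drugs: Tuple[str, ...] = tuple(drugs)
        self.effects: Tuple[str, ...] = tuple(effects)
        effect_set = set(self.effects)
        self._labels: Dict[str, FrozenSet[str]] = {}
        for d in self.drugs:
            labs = frozenset(labels.get(d, ()))
            unknown = labs - effect_set
            if unknown:
                raise ValueError(f"drug {d!r} labeled with unknown effects {unknown}")
            self._labels[d] = labs

    def effects_of(self, drug: str) -> FrozenSet[str]:
        return self._labels[drug]

    def has(self, drug: str, effect: str) -> bool:
        return effect in self._labels.get(drug, frozenset())

    def __contains__(self, drug: str) -> bool:
        return drug in self._labels

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_effects(self) -> int:
        return len(self.effects)

    def effect_counts(self) -> Dict[str, int]:
        """N(C_i): number of drugs carrying each effect."""
        counts = {e: 0 for e in self.effects}
        for labs in self._labels.values():
            for e in labs:
                counts[e] += 1
        return counts

    def drugs_with(self, effect: str) -> List[str]:
        return [d for d in self.drugs if effect in self._labels[d]]

    def subset(self, drugs: Iterable[str]) -> "LabelMatrix":
        """Restriction to the given drugs; effect order is preserved."""
        keep = [d for d in self.drugs if d in set(drugs)]
        return LabelMatrix(keep, self.effects, {d: self._labels[d] for d in keep})

    def pairs(self) -> Iterator[Tuple[str, str]]:
        for d in self.drugs:
            for e in self.effects:
                if e in self._labels[d]:
                    yield d, e

    def to_catalog(self, names: Mapping[str, str] | None = None) -> SideEffectCatalog:
        return SideEffectCatalog(
            effects=self.effects, counts=self.effect_counts(), names=names or {}
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LabelMatrix)
            and self.drugs == other.drugs
            and self.effects == other.effects
            and self._labels == other._labels
        )

    def __repr__(self) -> str:
        return f"LabelMatrix({self.n_drugs} drugs x {self.n_effects} effects)"


@dataclass
class ScoreVector:
    """Per-side-effect likelihood scores for one query drug.

    ``method`` records which scoring route produced the vector:
    ``direct`` (chemical-chemical sums), ``hybrid`` (shared-neighbor
    score sums) or ``similarity`` (max structural similarity).
    """

    drug: str
    scores: Dict[str, float]
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("direct", "hybrid", "similarity"):
            raise ValueError(f"unknown method tag {self.method!r}")
        neg = {e: s for e, s in self.scores.items() if s < 0}
        if neg:
            raise ValueError(f"negative scores: {neg}")

    def is_trivial(self) -> bool:
        """True when every entry is zero — no evidence of any kind."""
        return all(s == 0 for s in self.scores.values())


@dataclass
class RankedPrediction:
    """Ordered side-effect predictions for one query drug.

    ``items`` holds (rank, effect, score) triples with ranks consecutive
    from 1, scores strictly positive and non-increasing, effects unique.
    """

    drug: str
    items: List[Tuple[int, str, float]]
    method: str

    def __post_init__(self) -> None:
        prev = float("inf")
        seen = set()
        for k, (rank, effect, score) in enumerate(self.items, start=1):
            if rank != k:
                raise ValueError(f"ranks not consecutive at position {k}")
            if score <= 0:
                raise ValueError(f"non-positive score at rank {rank}")
            if score > prev:
                raise ValueError(f"scores increase at rank {rank}")
            if effect in seen:
                raise ValueError(f"duplicate effect {effect!r}")
            seen.add(effect)
            prev = score

    def effect_at(self, order: int) -> str | None:
        """Side effect ranked at ``order`` (1-based), or None past the end."""
        if 1 <= order <= len(self.items):
            return self.items[order - 1][1]
        return None

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class AccuracyProfile:
    """Order-wise accuracy AC(j) = P(j) / N for j = 1..m.

    P(j) counts evaluated drugs whose j-th ranked prediction is a true
    side effect; N is the number of structure-different drugs evaluated,
    kept fixed across orders (a missing j-th prediction is a miss).
    """

    hits: np.ndarray
    n_drugs: int
    mode: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.hits = np.asarray(self.hits, dtype=int)
        if self.n_drugs < 1:
            raise ValueError("profile needs at least one evaluated drug")
        if (self.hits < 0).any() or (self.hits > self.n_drugs).any():
            raise ValueError("hit counts must lie in [0, N]")

    @property
    def m(self) -> int:
        return len(self.hits)

    @property
    def accuracy(self) -> np.ndarray:
        return self.hits / self.n_drugs

    def ac(self, order: int) -> float:
        """AC(order), 1-based."""
        return float(self.hits[order - 1]) / self.n_drugs


@dataclass
class BenchmarkDataset:
    """Label matrix plus a recorded train/test split."""

    labels: LabelMatrix
    catalog: SideEffectCatalog
    train_drugs: Tuple[str, ...]
    test_drugs: Tuple[str, ...]
    split_seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_drugs), set(self.test_drugs)
        if tr & te:
            raise ValueError("train and test sets overlap")
        if tr | te != set(self.labels.drugs):
            raise ValueError("split is not a partition of the drugs")

    @property
    def train_labels(self) -> LabelMatrix:
        return self.labels.subset(self.train_drugs)

    @property
    def test_labels(self) -> LabelMatrix:
        return self.labels.subset(self.test_drugs)
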
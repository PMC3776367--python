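"""Synthetic fixture generator with planted guilt-by-association structure.

Drugs are partitioned into communities; each community owns a block of
characteristic side effects and a block of proteins.  Chemical-chemical
edges are dense inside communities and sparse across them, protein links
connect drugs to their community's proteins, and labels are drawn so that
community members share their characteristic effects — the premise that
interactive compounds share biological functions, in miniature.

A configurable fraction of drugs are "chemical orphans": their drug-drug
edges are withheld so they can only be reached through shared proteins,
exercising the hybrid fallback path.  The pairwise similarity table is
generated numerically (high within communities, low across); no real
chemical structures are involved.

Every random component (edges, protein links, labels, edge scores,
similarity) draws from its own child stream of the seed, so changing one
parameter perturbs only its component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np

from .containers import InteractionTable, LabelMatrix, ProteinChemicalTable
from .exceptions import GenerationError
from .similarity import PrecomputedProvider

_STREAMS = ("edges", "proteins", "labels", "scores", "similarity")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-community fixture.

    Defaults give 4 communities of 10 drugs over 10 side effects, dense
    within-community wiring (p_edge_within=0.8) with rare cross edges,
    strong but imperfect label sharing (p_label_within=0.9) plus light
    background labels, and confidence scores on the 150-999 range typical
    of medium-to-high-confidence interaction databases.  One drug in five
    is a chemical orphan reachable only through proteins, so the hybrid
    fallback is exercised while ~80% of drugs have direct evidence.
    """

    n_drugs: int = 40
    n_proteins: int = 12
    n_side_effects: int = 10
    n_communities: int = 4
    p_edge_within: float = 0.8
    p_edge_between: float = 0.05
    p_label_within: float = 0.9
    labels_per_drug: float = 3.0
    score_range: Tuple[float, float] = (150.0, 999.0)
    frac_chemical_orphans: float = 0.2
    p_protein_link: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_edge_within",
            "p_edge_between",
            "p_label_within",
            "frac_chemical_orphans",
            "p_protein_link",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_drugs", "n_proteins", "n_side_effects", "n_communities"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_communities > self.n_drugs:
            raise ValueError("more communities than drugs")
        lo, hi = self.score_range
        if not 0 <= lo <= hi:
            raise ValueError("score_range must satisfy 0 <= low <= high")


@dataclass
class Fixture:
    """A generated dataset plus its planted community structure."""

    spec: FixtureSpec
    cc: InteractionTable
    pc: ProteinChemicalTable
    labels: LabelMatrix
    provider: PrecomputedProvider
    community_of: Dict[str, int] = field(default_factory=dict)
    orphans: Set[str] = field(default_factory=set)


def _partition(items: List[str], k: int) -> List[List[str]]:
    """Round-robin partition into k blocks (sizes differ by at most 1)."""
    return [items[i::k] for i in range(k)]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the interaction tables, label matrix and similarity provider.

    Fully deterministic given ``spec.seed``; every drug is guaranteed at
    least one label (up to 100 redraws, then :class:`GenerationError`).
    """
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            _STREAMS, np.random.SeedSequence(spec.seed).spawn(len(_STREAMS))
        )
    }
    drugs = [f"D{i:03d}" for i in range(spec.n_drugs)]
    proteins = [f"P{i:03d}" for i in range(spec.n_proteins)]
    effects = [f"SE{i:02d}" for i in range(spec.n_side_effects)]

    communities = _partition(drugs, spec.n_communities)
    community_of = {d: c for c, block in enumerate(communities) for d in block}
    effect_blocks = _partition(effects, spec.n_communities)
    protein_blocks = _partition(proteins, spec.n_communities)

    rng_edges = streams["edges"]
    rng_scores = streams["scores"]
    lo, hi = spec.score_range

    def draw_score() -> float:
        return float(rng_scores.uniform(lo, hi))

    # chemical orphans: withheld from the drug-drug graph entirely
    n_orphans = int(round(spec.frac_chemical_orphans * spec.n_drugs))
    orphan_idx = (
        rng_edges.choice(spec.n_drugs, size=n_orphans, replace=False)
        if n_orphans
        else np.array([], dtype=int)
    )
    orphans = {drugs[i] for i in orphan_idx}

    cc = InteractionTable()
    for i in range(spec.n_drugs):
        for j in range(i + 1, spec.n_drugs):
            a, b = drugs[i], drugs[j]
            same = community_of[a] == community_of[b]
            p = spec.p_edge_within if same else spec.p_edge_between
            # one uniform draw per pair keeps the stream layout stable
            u = rng_edges.uniform()
            if u < p and a not in orphans and b not in orphans:
                cc.add(a, b, draw_score())

    rng_prot = streams["proteins"]
    pc = ProteinChemicalTable()
    for d in drugs:
        block = protein_blocks[community_of[d] % len(protein_blocks)]
        linked = [p for p in block if rng_prot.uniform() < spec.p_protein_link]
        if not linked and block:
            # every drug keeps at least one protein anchor so orphans stay
            # reachable through the hybrid route
            linked = [block[int(rng_prot.integers(len(block)))]]
        for p in linked:
            pc.add(p, d, draw_score())

    rng_labels = streams["labels"]
    char_expected = spec.p_label_within * (
        len(effects) / spec.n_communities
    )
    n_background = max(0, len(effects) - len(effect_blocks[0]))
    bg_rate = 0.0
    if n_background > 0 and spec.labels_per_drug > char_expected:
        bg_rate = min(
            1.0, (spec.labels_per_drug - char_expected) / n_background
        )
    label_map: Dict[str, Set[str]] = {}
    for d in drugs:
        char = effect_blocks[community_of[d] % len(effect_blocks)]
        others = [e for e in effects if e not in char]
        labs: Set[str] = set()
        for _ in range(100):
            labs = {e for e in char if rng_labels.uniform() < spec.p_label_within}
            labs |= {e for e in others if rng_labels.uniform() < bg_rate}
            if labs:
                break
        if not labs:
            raise GenerationError(
                f"could not draw a non-empty label set for {d} in 100 tries; "
                "raise p_label_within or labels_per_drug"
            )
        label_map[d] = labs
    labels = LabelMatrix(drugs, effects, label_map)

    rng_sim = streams["similarity"]
    table: Dict[Tuple[str, str], float] = {}
    for i in range(spec.n_drugs):
        for j in range(i + 1, spec.n_drugs):
            a, b = drugs[i], drugs[j]
            if community_of[a] == community_of[b]:
                s = float(rng_sim.uniform(0.6, 0.95))
            else:
                s = float(rng_sim.uniform(0.0, 0.3))
            table[(a, b)] = s
    provider = PrecomputedProvider(table)

    return Fixture(
        spec=spec,
        cc=cc,
        pc=pc,
        labels=labels,
        provider=provider,
        community_of=community_of,
        orphans=orphans,
    )


FIXTURE_FILES = {
    "chemical_links": "chemical_chemical.links.tsv",
    "protein_links": "protein_chemical.links.tsv",
    "labels": "drug_side_effects.tsv",
    "similarity": "similarity.tsv",
}


def write_fixture(fixture: Fixture, directory: str | Path) -> Dict[str, Path]:
    """Emit the fixture as the on-disk dialects the readers accept.

    Chemical links are written in both directions, as real interaction
    dumps do; reading the files back reproduces the fixture exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}

    with open(paths["chemical_links"], "w") as fh:
        fh.write(
            "chemical1\tchemical2\tsimilarity\texperimental\tdatabase"
            "\ttextmining\tcombined_score\n"
        )
        for a, b, s in sorted(fixture.cc.pairs()):
            for x, y in ((a, b), (b, a)):
                fh.write(f"{x}\t{y}\t0\t0\t0\t0\t{s!r}\n")

    with open(paths["protein_links"], "w") as fh:
        fh.write("chemical\tprotein\texperimental\tdatabase\ttextmining\tcombined_score\n")
        for p, c, s in sorted(fixture.pc.records()):
            fh.write(f"{c}\t{p}\t0\t0\t0\t{s!r}\n")

    with open(paths["labels"], "w") as fh:
        for d, e in fixture.labels.pairs():
            fh.write(f"{d}\t{e}\n")

    with open(paths["similarity"], "w") as fh:
        fh.write("drug_a\tdrug_b\tscore\n")
        for (a, b), s in sorted(fixture.provider.items().items()):
            fh.write(f"{a}\t{b}\t{s!r}\n")

    return paths
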
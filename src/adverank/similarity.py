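"""Structural similarity providers Q^s for the baseline ranker.

Two interchangeable backends satisfy the same contract — a symmetric
(drug, drug) -> [0, 1] score with Q^s(d, d) = 1 for a drug with a valid
structure:

* ``FingerprintProvider``: RDKit path-based (Daylight-style) fingerprints
  from SMILES, compared with the Tanimoto coefficient.
* ``PrecomputedProvider``: lookups in an externally computed pairwise
  table, for bit-exact reuse of scores from other toolkits.

A drug whose SMILES cannot be parsed scores 0 against everything (logged),
keeping the pipeline total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Optional, Protocol, Tuple

from .exceptions import StructureError, ValidationError

logger = logging.getLogger(__name__)


class SimilarityProvider(Protocol):
    """Contract: symmetric pairwise similarity in [0, 1]."""

    def similarity(self, a: str, b: str) -> float: ...


@dataclass(frozen=True)
class FingerprintParams:
    """Path-fingerprint parameters; recorded so fingerprints from different
    settings are never compared."""

    n_bits: int = 2048
    min_path: int = 1
    max_path: int = 7


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit set derived from a SMILES string."""

    bits: FrozenSet[int]
    params: FingerprintParams


def fingerprint_from_smiles(
    smiles: str, params: FingerprintParams = FingerprintParams()
) -> Fingerprint:
    """Deterministic path-based fingerprint of a molecule.

    Raises :class:`StructureError` for unparseable SMILES; callers may map
    that to similarity 0.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(
        mol,
        minPath=params.min_path,
        maxPath=params.max_path,
        fpSize=params.n_bits,
    )
    return Fingerprint(bits=frozenset(fp.GetOnBits()), params=params)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|bits(a) ∩ bits(b)| / |bits(a) ∪ bits(b)|.

    Two empty fingerprints are defined as identical (1.0); exactly one
    empty gives 0.0.  Fingerprints must share parameters.
    """
    if a.params != b.params:
        raise ValueError("fingerprints built with different parameters")
    if not a.bits and not b.bits:
        return 1.0
    if not a.bits or not b.bits:
        return 0.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


class FingerprintProvider:
    """Q^s backend computing Tanimoto similarity of path fingerprints.

    Built from an identifier -> SMILES map; fingerprints are computed
    once.  Unknown drugs and drugs with unparseable structures score 0
    against everything, and Q^s(d, d) = 1 for any drug with a valid
    structure.
    """

    backend = "fingerprint"

    def __init__(
        self,
        smiles: Mapping[str, str],
        params: FingerprintParams = FingerprintParams(),
    ) -> None:
        self.params = params
        self._fps: Dict[str, Optional[Fingerprint]] = {}
        for ident, smi in smiles.items():
            try:
                self._fps[ident] = fingerprint_from_smiles(smi, params)
            except StructureError:
                logger.warning(
                    "drug %r: unparseable SMILES %r; similarity degraded to 0",
                    ident,
                    smi,
                )
                self._fps[ident] = None

    def similarity(self, a: str, b: str) -> float:
        fa = self._fps.get(a)
        fb = self._fps.get(b)
        if fa is None or fb is None:
            return 0.0
        if a == b:
            return 1.0
        return tanimoto(fa, fb)


class PrecomputedProvider:
    """Q^s backend serving lookups from a pairwise score table.

    The table must be symmetric within 1e-9 and in [0, 1]; absent pairs
    score 0.  Self-similarity of a drug that appears in the table is 1.
    """

    backend = "precomputed"
    _ATOL = 1e-9

    def __init__(self, table: Mapping[Tuple[str, str], float]) -> None:
        self._scores: Dict[Tuple[str, str], float] = {}
        self._known: set = set()
        for (a, b), s in table.items():
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"similarity {s} for ({a!r}, {b!r}) outside [0, 1]"
                )
            key = (a, b) if a <= b else (b, a)
            prev = self._scores.get(key)
            if prev is not None and abs(prev - s) > self._ATOL:
                raise ValidationError(
                    f"asymmetric similarity for pair ({a!r}, {b!r}): "
                    f"{prev} vs {s}"
                )
            self._scores[key] = s if prev is None else prev
            self._known.update((a, b))

    def similarity(self, a: str, b: str) -> float:
        if a == b:
            return 1.0 if a in self._known else 0.0
        key = (a, b) if a <= b else (b, a)
        return self._scores.get(key, 0.0)

    def items(self) -> Dict[Tuple[str, str], float]:
        """Canonical (a <= b) pair -> score entries."""
        return dict(self._scores)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PrecomputedProvider)
            and self._scores == other._scores
        )


def precomputed_provider(
    table: Mapping[Tuple[str, str], float]
) -> PrecomputedProvider:
    """Build a validated provider from a pairwise score table."""
    return PrecomputedProvider(table)
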
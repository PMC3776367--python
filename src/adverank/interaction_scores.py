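"""Neighbor-set algebra over the interaction tables and the hybrid score.

Direct evidence lives in the chemical-chemical table (Q^c) and the
protein-chemical table (Q^p).  When two drugs share no direct edge, their
likelihood of interaction is estimated from the neighbors they share: the
hybrid score averages, over the union of shared chemical neighbors and
shared protein partners, the two confidence scores each shared entity
carries toward the pair,

    Q^h(d1, d2) = [ sum_{d' in Ic(d1,d2)} (Q^c(d1,d') + Q^c(d2,d'))
                  + sum_{p' in Ip(d1,d2)} (Q^p(p',d1) + Q^p(p',d2)) ]
                  / (2 |Ic(d1,d2) ∪ Ip(d1,d2)|),

with the empty-union case defined as 0 (no shared evidence).  Chemical and
protein identifiers are tagged before the union so the two namespaces can
never collide; the denominator therefore equals 2(|Ic∩| + |Ip∩|).
"""

from __future__ import annotations

from typing import FrozenSet, Set, Tuple

from .containers import InteractionTable, ProteinChemicalTable


def chemical_neighbors(d: str, cc: InteractionTable) -> Set[str]:
    """I^c(d): drugs with strictly positive interaction score against d."""
    return {x for x, s in cc.neighbors(d).items() if s > 0}


def protein_neighbors(d: str, pc: ProteinChemicalTable) -> Set[str]:
    """I^p(d): proteins with strictly positive interaction score against d."""
    return {p for p, s in pc.proteins_of(d).items() if s > 0}


def shared_neighbors(
    d1: str,
    d2: str,
    cc: InteractionTable,
    pc: ProteinChemicalTable,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """(I^c(d1,d2), I^p(d1,d2)): shared chemical and protein neighbors."""
    shared_c = chemical_neighbors(d1, cc) & chemical_neighbors(d2, cc)
    shared_p = protein_neighbors(d1, pc) & protein_neighbors(d2, pc)
    return frozenset(shared_c), frozenset(shared_p)


def hybrid_score(
    d1: str,
    d2: str,
    cc: InteractionTable,
    pc: ProteinChemicalTable,
) -> float:
    """Q^h(d1, d2): shared-neighbor likelihood of interaction.

    Symmetric in its drug arguments, non-negative, 0 when the pair shares
    no neighbor of either kind, and never exceeding the largest single
    confidence score in the tables (each union member contributes the
    mean of two such scores).
    """
    shared_c, shared_p = shared_neighbors(d1, d2, cc, pc)
    denom = 2 * (len(shared_c) + len(shared_p))
    if denom == 0:
        return 0.0
    total = 0.0
    for dp in shared_c:
        total += cc.score(d1, dp) + cc.score(d2, dp)
    for pp in shared_p:
        total += pc.score(pp, d1) + pc.score(pp, d2)
    return total / denom
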
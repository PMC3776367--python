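"""Independent brute-force reference implementations.

Everything here works on plain dictionaries and explicit loops, never on
the package's containers or algorithms, so agreement with the package is
a genuine cross-check.  Interaction scores in the generated instances are
integer-valued, making sums exact in floating point regardless of
summation order.

Naive table formats:
  cc: dict[(a, b)] -> score, listing BOTH directions of every edge
  pc: dict[(protein, chemical)] -> score
  labels: dict[drug] -> set of effects
"""

from typing import Dict, List, Optional, Sequence, Set, Tuple


def naive_chemical_neighbors(d: str, cc: Dict[Tuple[str, str], float]) -> Set[str]:
    out = set()
    for (a, b), s in cc.items():
        if s > 0:
            if a == d:
                out.add(b)
            if b == d:
                out.add(a)
    out.discard(d)
    return out


def naive_protein_neighbors(d: str, pc: Dict[Tuple[str, str], float]) -> Set[str]:
    return {p for (p, c), s in pc.items() if c == d and s > 0}


def cc_score(cc: Dict[Tuple[str, str], float], a: str, b: str) -> float:
    return max(cc.get((a, b), 0.0), cc.get((b, a), 0.0))


def naive_hybrid_score(
    d1: str,
    d2: str,
    cc: Dict[Tuple[str, str], float],
    pc: Dict[Tuple[str, str], float],
) -> float:
    shared_c = sorted(naive_chemical_neighbors(d1, cc) & naive_chemical_neighbors(d2, cc))
    shared_p = sorted(naive_protein_neighbors(d1, pc) & naive_protein_neighbors(d2, pc))
    denom = 2 * (len(shared_c) + len(shared_p))
    if denom == 0:
        return 0.0
    total = 0.0
    for dp in shared_c:
        total += cc_score(cc, d1, dp) + cc_score(cc, d2, dp)
    for pp in shared_p:
        total += pc.get((pp, d1), 0.0) + pc.get((pp, d2), 0.0)
    return total / denom


def naive_score_direct(
    d: str,
    train_labels: Dict[str, Set[str]],
    effects: Sequence[str],
    cc: Dict[Tuple[str, str], float],
) -> Dict[str, float]:
    scores = {}
    for e in effects:
        total = 0.0
        for di, labs in train_labels.items():
            if di == d:
                continue
            c_ij = 1 if e in labs else 0
            total += cc_score(cc, d, di) * c_ij
        scores[e] = total
    return scores


def naive_score_hybrid(
    d: str,
    train_labels: Dict[str, Set[str]],
    effects: Sequence[str],
    cc: Dict[Tuple[str, str], float],
    pc: Dict[Tuple[str, str], float],
) -> Dict[str, float]:
    scores = {}
    for e in effects:
        total = 0.0
        for di, labs in train_labels.items():
            if di == d:
                continue
            c_ij = 1 if e in labs else 0
            total += naive_hybrid_score(d, di, cc, pc) * c_ij
        scores[e] = total
    return scores


def naive_score_similarity(
    d: str,
    train_labels: Dict[str, Set[str]],
    effects: Sequence[str],
    sim: Dict[Tuple[str, str], float],
) -> Dict[str, float]:
    def lookup(a, b):
        return max(sim.get((a, b), 0.0), sim.get((b, a), 0.0))

    scores = {}
    for e in effects:
        best = 0.0
        for di, labs in train_labels.items():
            if di == d or e not in labs:
                continue
            best = max(best, lookup(d, di))
        scores[e] = best
    return scores


def naive_accuracy_profile(
    predictions: Dict[str, List[str]],
    truth: Dict[str, Set[str]],
    m: int,
) -> Tuple[List[int], int]:
    """(P(j) for j=1..m, N) from ordered effect lists per drug."""
    n = len(predictions)
    hits = [0] * m
    for drug, ordered in predictions.items():
        for j in range(1, m + 1):
            if j <= len(ordered) and ordered[j - 1] in truth[drug]:
                hits[j - 1] += 1
    return hits, n
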
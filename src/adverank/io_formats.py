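"""Readers and writers for the external file dialects.

Interaction inputs follow the STITCH detailed-links dialects: tab-separated
with a header row, one interaction per line, several evidence-channel
scores and an integrated ``combined_score`` column.  Real dumps list every
chemical-chemical edge in both directions; the reader collapses the two
directions (and any duplicates) by keeping the maximum score, drops
self-loops, and keeps only rows whose score exceeds ``min_score``
(exclusive — positive combined scores denote interactive pairs).

Labels are a plain two-column drug/side-effect TSV; SMILES input uses the
usual ``.smi`` convention (SMILES string, whitespace, identifier).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd

from .containers import (
    AccuracyProfile,
    InteractionTable,
    ProteinChemicalTable,
    RankedPrediction,
)
from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SCORE_COLUMN = "combined_score"


#: canonical column orders of the two STITCH detailed-links dialects,
#: used when a file turns out to have no header row
CHEMICAL_LINK_COLUMNS = (
    "chemical1", "chemical2", "similarity", "experimental",
    "database", "textmining", "combined_score",
)
PROTEIN_LINK_COLUMNS = (
    "chemical", "protein", "experimental", "database",
    "textmining", "combined_score",
)


def _is_header_row(fields: List[str]) -> bool:
    # Score fields (columns 3+) in a header are names; in data they are
    # numbers.  A first row whose trailing fields are all numeric is data.
    def numeric(x: str) -> bool:
        try:
            float(x)
            return True
        except ValueError:
            return False

    return not all(numeric(x) for x in fields[2:]) if len(fields) > 2 else True


def _read_scored_tsv(
    path: str | Path,
    key_columns: Tuple[str, str],
    score_column: str,
    canonical_columns: Tuple[str, ...],
) -> pd.DataFrame:
    """Read a STITCH-dialect TSV down to (key_a, key_b, score) rows."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: file is empty (expected a header row)")
    if _is_header_row(first.rstrip("\n").split("\t")):
        df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] != len(canonical_columns):
            raise FormatError(
                f"{path}: headerless file has {df.shape[1]} columns; "
                f"expected {len(canonical_columns)}"
            )
        df.columns = list(canonical_columns)
    for col in (*key_columns, score_column):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )
    def parse(x):
        # Python's float() is correctly rounded; pandas' fast parser is not,
        # which would break exact write/read round trips.
        try:
            return float(x)
        except (TypeError, ValueError):
            return None

    scores = df[score_column].map(parse)
    bad = scores.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(
            f"{path}: non-numeric {score_column!r} value on line {line}"
        )
    neg = scores < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ValidationError(
            f"{path}: negative {score_column!r} value on line {line}"
        )
    out = df[list(key_columns)].copy()
    out["score"] = scores.astype(float)
    return out


def read_chemical_links(
    path: str | Path,
    score_column: str = DEFAULT_SCORE_COLUMN,
    min_score: float = 0.0,
) -> InteractionTable:
    """Load a chemical-chemical links file into a symmetric table.

    Rows with score <= ``min_score`` are discarded, self-loops dropped,
    and duplicate or bidirectional listings of the same unordered pair
    collapsed by the maximum score.  Row order never matters.
    """
    df = _read_scored_tsv(
        path, ("chemical1", "chemical2"), score_column, CHEMICAL_LINK_COLUMNS
    )
    table = InteractionTable()
    n_self = 0
    for a, b, s in df.itertuples(index=False):
        if a == b:
            n_self += 1
            continue
        if s > min_score:
            table.add(a, b, s)
    if n_self:
        logger.info("%s: dropped %d self-interaction rows", path, n_self)
    return table


def read_protein_links(
    path: str | Path,
    score_column: str = DEFAULT_SCORE_COLUMN,
    min_score: float = 0.0,
) -> ProteinChemicalTable:
    """Load a protein-chemical links file; duplicates keep the max score."""
    df = _read_scored_tsv(
        path, ("chemical", "protein"), score_column, PROTEIN_LINK_COLUMNS
    )
    table = ProteinChemicalTable()
    for c, p, s in df.itertuples(index=False):
        if s > min_score:
            table.add(p, c, s)
    return table


def read_label_table(path: str | Path) -> List[Tuple[str, str]]:
    """Read a two-column drug/side-effect TSV into deduplicated pairs.

    First-seen order of pairs (hence of drugs and effects) is preserved.
    """
    path = Path(path)
    pairs: List[Tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: expected 2 tab-separated columns on line "
                    f"{lineno}, got {len(fields)}"
                )
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


def read_smiles(path: str | Path) -> Dict[str, str]:
    """Read a ``.smi`` file into an identifier -> SMILES map.

    Blank lines and ``#`` comments are skipped; a duplicated identifier
    keeps the last occurrence (with a warning).
    """
    path = Path(path)
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 1)
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno} has a SMILES string but no identifier"
                )
            smiles, ident = fields[0], fields[1].strip()
            if ident in out:
                logger.warning(
                    "%s: duplicate identifier %r on line %d; keeping the later entry",
                    path,
                    ident,
                    lineno,
                )
            out[ident] = smiles
    return out


def read_similarity_table(path: str | Path) -> Dict[Tuple[str, str], float]:
    """Read a precomputed pairwise similarity TSV (drug_a, drug_b, score).

    Returns raw directed entries; validation (symmetry, range) is done by
    the precomputed provider.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"drug_a": str, "drug_b": str},
        float_precision="round_trip",
    )
    for col in ("drug_a", "drug_b", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return {
        (a, b): float(s) for a, b, s in df[["drug_a", "drug_b", "score"]].itertuples(index=False)
    }


PREDICTION_COLUMNS = ("drug", "rank", "side_effect", "score", "method")


def write_predictions(
    predictions: Iterable[RankedPrediction], path: str | Path
) -> None:
    """Write ranked predictions to TSV, one row per (drug, rank, effect)."""
    rows = []
    for pred in predictions:
        for rank, effect, score in pred.items:
            rows.append((pred.drug, rank, effect, repr(score), pred.method))
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> List[RankedPrediction]:
    """Inverse of :func:`write_predictions`; round-trips losslessly."""
    df = pd.read_csv(
        path, sep="\t", dtype={"drug": str, "side_effect": str},
        float_precision="round_trip",
    )
    preds: List[RankedPrediction] = []
    if df.empty:
        return preds
    for drug, grp in df.groupby("drug", sort=False):
        items = [
            (int(r), str(e), float(s))
            for r, e, s in grp[["rank", "side_effect", "score"]].itertuples(index=False)
        ]
        preds.append(
            RankedPrediction(drug=str(drug), items=items, method=str(grp["method"].iloc[0]))
        )
    return preds


PROFILE_COLUMNS = ("order", "hits", "n", "accuracy")


def write_accuracy_profile(profile: AccuracyProfile, path: str | Path) -> None:
    """Write an order-wise accuracy profile to TSV (order, P(j), N, AC(j))."""
    rows = [
        (j + 1, int(profile.hits[j]), profile.n_drugs, repr(float(profile.accuracy[j])))
        for j in range(profile.m)
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_accuracy_profile(path: str | Path) -> AccuracyProfile:
    """Inverse of :func:`write_accuracy_profile`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        raise FormatError(f"{path}: empty accuracy profile")
    n = int(df["n"].iloc[0])
    return AccuracyProfile(hits=df["hits"].to_numpy(dtype=int), n_drugs=n)


def write_label_table(pairs: Iterable[Tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, e in pairs:
            fh.write(f"{d}\t{e}\n")


def write_catalog(
    catalog_counts: Mapping[str, int], path: str | Path
) -> None:
    """Write the side-effect catalog with per-effect drug counts N(C_i)."""
    with open(path, "w") as fh:
        fh.write("side_effect\tn_drugs\n")
        for effect, count in catalog_counts.items():
            fh.write(f"{effect}\t{count}\n")
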
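"""Consistency-based taxonomic assignment of genome bins.

Each protein-coding gene of a bin gets a taxon vote from its filtered
alignment hits against a reference protein database (hits arrive as
BLAST outfmt-6 rows with lineage columns appended). Filters: E-value
<= 1e-5, sequence identity > 60%, query coverage > 50%, and at most 100
hits per gene. Votes are cast at the genus rank; the modal taxon's share
of the voting genes is the bin's CONSISTENCY. A bin is identified at
genus when consistency exceeds 65%; otherwise votes are recomputed at
the family rank and the same test applied; otherwise the bin is
unclassified. A bin none of whose genes has any database match is
unclassified with consistency reported as 100 (no dissent among zero
voters), which flags potential novel lineages rather than poor bins.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from collections import Counter
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .synthetic import GENE_HIT_COLUMNS, LINEAGE_COLUMNS

__all__ = [
    "Rank",
    "HitFilterParams",
    "TaxonAssignment",
    "read_gene_hits",
    "scaffold_of_gene",
    "filter_hits",
    "gene_taxon",
    "gene_votes",
    "assign_bin",
]

CONSISTENCY_THRESHOLD = 65.0
_MISSING = {"", "NA", "N/A", "NONE", "UNCLASSIFIED"}


class Rank(str, enum.Enum):
    GENUS = "genus"
    FAMILY = "family"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HitFilterParams:
    max_evalue: float = 1e-5
    min_identity: float = 60.0      # strict >
    min_query_coverage: float = 50.0  # strict >
    max_hits_per_gene: int = 100


@dataclass(frozen=True)
class TaxonAssignment:
    """Outcome of the bin-level vote."""

    bin_label: str
    rank: Rank
    taxon: str | None
    consistency: float
    n_assigned_genes: int


def read_gene_hits(path: str | Path, on_malformed: str = "error") -> pd.DataFrame:
    """Read a headerless gene-hit TSV (12 outfmt-6 + 6 lineage columns).

    ``on_malformed='skip'`` drops rows that fail to parse, reporting their
    line numbers on stderr; the default is fatal with line numbers.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=list(GENE_HIT_COLUMNS), dtype=str,
            on_bad_lines="error" if on_malformed == "error" else "skip",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed hit table {path}: {exc}") from exc
    numeric = ["pident", "length", "mismatch", "gapopen", "qstart", "qend",
               "sstart", "send", "evalue", "bitscore"]
    coerced = df.copy()
    for col in numeric:
        coerced[col] = pd.to_numeric(df[col], errors="coerce")
    bad = coerced[numeric].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        if on_malformed == "error":
            raise ValueError(f"malformed rows in {path} at lines {lines[:10]}")
        import sys
        print(f"skipping {bad.sum()} malformed rows (lines {lines[:10]}...)",
              file=sys.stderr)
        coerced = coerced[~bad]
    return coerced.reset_index(drop=True)


def scaffold_of_gene(gene_id: str) -> str:
    """Scaffold id of a gene, by the ORF-caller convention scaffold_id + '_' + n."""
    sid, _, ordinal = gene_id.rpartition("_")
    if not sid or not ordinal.isdigit():
        raise ValueError(
            f"gene id {gene_id!r} does not follow the <scaffold>_<n> convention"
        )
    return sid


def _with_query_coverage(hits: pd.DataFrame) -> pd.DataFrame:
    # outfmt-6 lacks query length; use the longest observed alignment end
    # per gene as the query length (one near-full-length hit is typical)
    hits = hits.copy()
    qlen = hits.groupby("qseqid")["qend"].transform("max").astype(float)
    hits["query_coverage"] = 100.0 * (hits["qend"] - hits["qstart"] + 1) / qlen
    return hits


def filter_hits(
    hits: pd.DataFrame, params: HitFilterParams = HitFilterParams()
) -> pd.DataFrame:
    """Apply the alignment-quality filters and the per-gene hit cap.

    Retained iff evalue <= max_evalue AND identity > min_identity AND
    query coverage > min_query_coverage; then at most
    ``max_hits_per_gene`` best rows per gene by bitscore (ties: lower
    E-value, then file order). Row order of the output is the stable
    per-gene ranking used for all later vote computations.
    """
    hits = _with_query_coverage(hits)
    keep = (
        (hits["evalue"] <= params.max_evalue)
        & (hits["pident"] > params.min_identity)
        & (hits["query_coverage"] > params.min_query_coverage)
    )
    retained = hits[keep].copy()
    retained["_order"] = np.arange(len(retained))
    retained = retained.sort_values(
        ["qseqid", "bitscore", "evalue", "_order"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    retained = retained.groupby("qseqid", sort=False).head(params.max_hits_per_gene)
    return retained.drop(columns="_order").reset_index(drop=True)


def gene_taxon(gene_rows: pd.DataFrame, rank: Rank) -> str | None:
    """Taxon vote of one gene at ``rank``: the best-scoring labeled hit.

    ``gene_rows`` is the retained hits of one gene (ranking is redone
    here: bitscore descending, then E-value ascending, then input
    order). Returns None when no retained row carries a label at the
    rank.
    """
    if rank not in (Rank.GENUS, Rank.FAMILY):
        raise ValueError(f"votes are cast at genus or family, not {rank}")
    ranked = gene_rows.sort_values(
        ["bitscore", "evalue"], ascending=[False, True], kind="mergesort"
    )
    for label in ranked[rank.value]:
        if isinstance(label, str) and label.strip().upper() not in _MISSING:
            return label.strip()
    return None


def gene_votes(
    filtered_hits: pd.DataFrame,
    rank: Rank,
    method: Literal["best_hit", "fractional"] = "best_hit",
) -> dict[str, Counter]:
    """Per-gene taxon votes at ``rank`` over a filtered hit table.

    ``best_hit`` (default): each gene votes once, for its best labeled
    hit. ``fractional``: each gene's vote is split evenly over the labels
    of all its retained hits. Returns gene_id -> Counter of vote weight.
    """
    votes: dict[str, Counter] = {}
    col = rank.value
    for gid, rows in filtered_hits.groupby("qseqid", sort=False):
        labels = [
            lab.strip() for lab in rows[col]
            if isinstance(lab, str) and lab.strip().upper() not in _MISSING
        ]
        if not labels:
            continue
        if method == "best_hit":
            votes[gid] = Counter({labels[0]: 1.0})
        else:
            w = 1.0 / len(labels)
            votes[gid] = Counter()
            for lab in labels:
                votes[gid][lab] += w
    return votes


def _tally(votes: dict[str, Counter]) -> tuple[str | None, float, int]:
    """Modal taxon, its consistency %, and the voting-gene count."""
    total = Counter()
    for v in votes.values():
        total.update(v)
    n_voting = len(votes)
    if n_voting == 0:
        return None, 100.0, 0
    # modal taxon; lexicographic tie-break for determinism
    taxon = max(sorted(total), key=lambda t: total[t])
    return taxon, 100.0 * total[taxon] / n_voting, n_voting


def assign_bin(
    bin_label: str,
    bin_filtered_hits: pd.DataFrame,
    method: Literal["best_hit", "fractional"] = "best_hit",
    threshold: float = CONSISTENCY_THRESHOLD,
) -> TaxonAssignment:
    """Vote a bin's genes into a taxon with the rank-fallback rule.

    Genus first: if the modal genus holds more than ``threshold`` percent
    of the voting genes the bin is identified at genus. Otherwise votes
    are recomputed from the hits at family rank (a family can reunite
    split genera) and tested the same way. Failing both, the bin is
    unclassified, reporting the better of the two modal fractions. Zero
    voting genes gives unclassified with consistency 100.
    """
    genus_votes = gene_votes(bin_filtered_hits, Rank.GENUS, method)
    taxon, consistency, n = _tally(genus_votes)
    if n == 0:
        return TaxonAssignment(bin_label, Rank.UNCLASSIFIED, None, 100.0, 0)
    if consistency > threshold:
        return TaxonAssignment(bin_label, Rank.GENUS, taxon, consistency, n)
    fam_votes = gene_votes(bin_filtered_hits, Rank.FAMILY, method)
    fam_taxon, fam_consistency, fam_n = _tally(fam_votes)
    if fam_n > 0 and fam_consistency > threshold:
        return TaxonAssignment(bin_label, Rank.FAMILY, fam_taxon,
                               fam_consistency, fam_n)
    return TaxonAssignment(
        bin_label, Rank.UNCLASSIFIED, None, max(consistency, fam_consistency), n
    )
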
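"""Bin quality rating and coverage-weighted community composition.

The five-tier rubric grades each bin on four numbers — marker-set
completeness, contamination, taxonomic consistency, and contig count:

=================  =====  ==========================================================
category           stars  criteria (completeness / contamination / consistency / contigs)
NEARLY_COMPLETE    5      >=95 / <=5 / >=90 / <=10, or >=90 / <=5 / >=80 / <=3
GOOD_DRAFT         4      >=90 / <=5 / >=80
MODERATE_DRAFT     3      >=70 / <=10 / >=65
PARTIAL            2      >=50 / <=15 / >=65
DISQUALIFIED       1      anything else (mixed or fractional sequences)
=================  =====  ==========================================================

Thresholds are inclusive on their attainable side (>= for completeness
and consistency, <= for contamination and contigs), the only reading
under which the tiers nest. Relative abundance is each bin's share of
community sequence mass, sum(length x coverage), a proxy for its share
of the read pool; unassigned scaffolds are excluded from the
denominator by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assembly import Scaffold
from .binning import BinAssignment, UNASSIGNED
from .markers import MarkerProfile
from .taxonomy import TaxonAssignment, Rank

__all__ = [
    "QualityCategory",
    "QualityRating",
    "rate_bin",
    "relative_abundance",
    "community_report",
    "STAR_OF",
]


class QualityCategory(enum.IntEnum):
    """Bin quality tiers; higher is better."""

    DISQUALIFIED = 1
    PARTIAL = 2
    MODERATE_DRAFT = 3
    GOOD_DRAFT = 4
    NEARLY_COMPLETE = 5


STAR_OF = {c: "*" * int(c) for c in QualityCategory}


@dataclass(frozen=True)
class QualityRating:
    category: QualityCategory
    criteria_trace: str

    @property
    def stars(self) -> str:
        return STAR_OF[self.category]


def rate_bin(
    completeness: float,
    contamination: float,
    consistency: float,
    n_contigs: int,
) -> QualityRating:
    """Grade one bin; returns the tier and which rule fired."""
    for v, name in ((completeness, "completeness"), (contamination, "contamination"),
                    (consistency, "consistency")):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError(f"{name} must be finite, got {v}")
    if n_contigs < 1:
        raise ValueError("a bin has at least one contig")
    if completeness >= 95 and contamination <= 5 and consistency >= 90 and n_contigs <= 10:
        return QualityRating(QualityCategory.NEARLY_COMPLETE,
                             "nearly-complete rule 1: >=95/<=5/>=90/<=10 contigs")
    if completeness >= 90 and contamination <= 5 and consistency >= 80 and n_contigs <= 3:
        return QualityRating(QualityCategory.NEARLY_COMPLETE,
                             "nearly-complete rule 2: >=90/<=5/>=80/<=3 contigs")
    if completeness >= 90 and contamination <= 5 and consistency >= 80:
        return QualityRating(QualityCategory.GOOD_DRAFT,
                             "good draft: >=90/<=5/>=80")
    if completeness >= 70 and contamination <= 10 and consistency >= 65:
        return QualityRating(QualityCategory.MODERATE_DRAFT,
                             "moderate draft: >=70/<=10/>=65")
    if completeness >= 50 and contamination <= 15 and consistency >= 65:
        return QualityRating(QualityCategory.PARTIAL,
                             "partial genome or pangenome: >=50/<=15/>=65")
    return QualityRating(QualityCategory.DISQUALIFIED,
                         "not meeting any criteria set")


def relative_abundance(
    assignment: BinAssignment,
    scaffolds: Sequence[Scaffold],
    include_unassigned: bool = False,
) -> dict[str, float]:
    """Percent of community sequence mass per bin.

    mass(bin) = sum over member scaffolds of length x coverage; percents
    are mass fractions of the binned total (or of everything when
    ``include_unassigned``). Scale-invariant in coverage.
    """
    mass: dict[str, float] = {}
    for s in scaffolds:
        b = assignment.bin_of.get(s.scaffold_id, UNASSIGNED)
        mass[b] = mass.get(b, 0.0) + s.length * s.coverage
    if not include_unassigned:
        mass.pop(UNASSIGNED, None)
    total = sum(mass.values())
    if total <= 0:
        raise ValueError("zero total sequence mass; nothing is binned")
    return {b: 100.0 * m / total for b, m in mass.items() if b != UNASSIGNED}


def community_report(
    assignment: BinAssignment,
    scaffolds: Sequence[Scaffold],
    profiles: Mapping[str, MarkerProfile],
    taxa: Mapping[str, TaxonAssignment],
    ratings: Mapping[str, QualityRating],
    abundances: Mapping[str, float],
    sample_id: str = "sample",
) -> pd.DataFrame:
    """One row per bin: size, abundance, taxon, rating; plus a totals row.

    Rows are ordered by ascending abundance within the sample. All five
    inputs must cover exactly the assignment's bins; a missing key is an
    error naming the bin.
    """
    bins = assignment.bins
    for name, mapping in (("profile", profiles), ("taxon", taxa),
                          ("rating", ratings), ("abundance", abundances)):
        missing = [b for b in bins if b not in mapping]
        if missing:
            raise KeyError(f"missing {name} for bin(s) {missing}")
    by_scaffold = {s.scaffold_id: s for s in scaffolds}
    rows = []
    for b in bins:
        members = assignment.members(b)
        size_mb = sum(by_scaffold[s].length for s in members) / 1e6
        t = taxa[b]
        taxon_str = t.taxon if t.rank != Rank.UNCLASSIFIED else "Unclassified"
        rows.append({
            "Sample": sample_id,
            "Genome Bin ID": b,
            "Genome Bin Size (Mb)": round(size_mb, 2),
            "Relative abundance (%)": round(abundances[b], 2),
            "Taxonomic assignment": taxon_str,
            "Assignment rank": t.rank.value,
            "Consistency (%)": round(t.consistency, 2),
            "Completeness (%)": round(profiles[b].completeness, 2),
            "Contamination (%)": round(profiles[b].contamination, 2),
            "Contigs": len(members),
            "Quality rating": ratings[b].stars,
        })
    rows.sort(key=lambda r: (r["Relative abundance (%)"], r["Genome Bin ID"]))
    df = pd.DataFrame(rows)
    total = {
        "Sample": sample_id,
        "Genome Bin ID": "TOTAL",
        "Genome Bin Size (Mb)": round(df["Genome Bin Size (Mb)"].sum(), 2),
        "Relative abundance (%)": round(df["Relative abundance (%)"].sum(), 2),
        "Taxonomic assignment": "",
        "Assignment rank": "",
        "Consistency (%)": "",
        "Completeness (%)": "",
        "Contamination (%)": "",
        "Contigs": int(df["Contigs"].sum()),
        "Quality rating": "",
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
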
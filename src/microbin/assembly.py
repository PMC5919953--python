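"""Scaffold records, assembly statistics, and the length/coverage filter.

Scaffolds are the atomic unit of the whole pipeline: each carries its
sequence, mean read depth, and a sample tag. Assemblies are summarized
with the usual statistics (N50, total length, mean GC), and filtered at
a minimum length of 200 bp and minimum mean coverage of 3x before
binning; both boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Scaffold",
    "AssemblySummary",
    "gc_fraction",
    "read_scaffolds",
    "write_scaffolds",
    "filter_scaffolds",
    "n50",
    "summarize_assembly",
]

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class Scaffold:
    """One assembled scaffold with its mean read depth.

    ``gc`` is the G+C fraction of the unambiguous bases; ``N`` counts
    toward neither numerator nor denominator.
    """

    scaffold_id: str
    sequence: str
    coverage: float
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not np.isfinite(self.coverage) or self.coverage < 0:
            raise ValueError(
                f"scaffold {self.scaffold_id!r}: coverage must be finite and >= 0, "
                f"got {self.coverage!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass(frozen=True)
class AssemblySummary:
    n_scaffolds: int
    total_length: int
    n50: int
    mean_gc: float
    max_length: int


def gc_fraction(sequence: str) -> float:
    """G+C fraction over the unambiguous bases of ``sequence``.

    The alphabet is {A, C, G, T, N} (case-insensitive); ``N`` is excluded
    from both numerator and denominator. Raises ``ValueError`` for empty,
    all-N, or out-of-alphabet input.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("sequence is all-N; GC fraction undefined")
    return gc / acgt


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (scaffold_id <TAB> mean_depth) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold_id", "mean_depth"],
                     dtype={"scaffold_id": str})
    if df["scaffold_id"].duplicated().any():
        dups = df.loc[df["scaffold_id"].duplicated(), "scaffold_id"].tolist()
        raise ValueError(f"duplicate scaffold ids in coverage table: {dups[:5]}")
    return dict(zip(df["scaffold_id"], df["mean_depth"].astype(float)))


def read_scaffolds(
    fasta_path: str | Path,
    coverage_path: str | Path,
    sample_id: str = "sample",
) -> list[Scaffold]:
    """Load scaffolds from FASTA and attach per-scaffold mean coverage.

    Every FASTA record id must appear in the coverage table; a missing or
    duplicate id is an error naming the offending record.
    """
    coverage = read_coverage_table(coverage_path)
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in coverage:
            raise KeyError(f"no coverage entry for FASTA record {rec.id!r}")
        scaffolds.append(
            Scaffold(rec.id, str(rec.seq).upper(), coverage[rec.id], sample_id)
        )
    return scaffolds


def write_scaffolds(
    scaffolds: Iterable[Scaffold],
    fasta_path: str | Path,
    coverage_path: str | Path,
) -> None:
    """Write scaffolds as 80-column-wrapped FASTA plus a coverage TSV."""
    scaffolds = list(scaffolds)
    records = [
        SeqRecord(Seq(s.sequence), id=s.scaffold_id, description="")
        for s in scaffolds
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)
    with open(coverage_path, "w") as fh:
        for s in scaffolds:
            fh.write(f"{s.scaffold_id}\t{s.coverage:.6g}\n")


def filter_scaffolds(
    scaffolds: Iterable[Scaffold],
    min_length: int = 200,
    min_coverage: float = 3.0,
) -> list[Scaffold]:
    """Keep scaffolds with length >= ``min_length`` and coverage >= ``min_coverage``.

    Both boundaries are inclusive (the stated minima are attainable).
    """
    if min_length < 0 or min_coverage < 0:
        raise ValueError("filter thresholds must be >= 0")
    return [s for s in scaffolds if s.length >= min_length and s.coverage >= min_coverage]


def n50(lengths: Sequence[int]) -> int:
    """N50 of a multiset of contig lengths.

    Largest length L such that contigs of length >= L together hold at
    least half of the total assembly length: sort descending, take the
    length at which the cumulative sum first reaches total/2.
    """
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("n50 of an empty length multiset is undefined")
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2, side="left"))
    return int(arr[idx])


def summarize_assembly(scaffolds: Sequence[Scaffold]) -> AssemblySummary:
    """Assembly statistics table row: count, total length, N50, mean GC, max length.

    ``mean_gc`` is length-weighted over unambiguous bases (GC of the
    concatenated assembly).
    """
    if not scaffolds:
        raise ValueError("cannot summarize an empty assembly")
    lengths = [s.length for s in scaffolds]
    gc_bases = 0
    acgt_bases = 0
    for s in scaffolds:
        seq = s.sequence.upper()
        gc_bases += seq.count("G") + seq.count("C")
        acgt_bases += len(seq) - seq.count("N")
    return AssemblySummary(
        n_scaffolds=len(scaffolds),
        total_length=int(sum(lengths)),
        n50=n50(lengths),
        mean_gc=gc_bases / acgt_bases,
        max_length=int(max(lengths)),
    )
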
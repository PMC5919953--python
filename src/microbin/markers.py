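"""Completeness and contamination from a 107-gene single-copy marker census.

A bacterial genome is expected to carry each of 107 essential
single-copy genes exactly once, so the census of those markers over a
genome bin doubles as a quality estimate:

* completeness  = 100 * (distinct markers present) / 107
* contamination = 100 * (marker copies beyond the first) / 107

Contamination counts extra copies (CheckM-style), so it can exceed 100
for badly mixed bins. The concrete marker identity list is a replaceable
configuration file; a synthetic stand-in universe ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MarkerProfile",
    "load_marker_universe",
    "default_marker_universe",
    "read_marker_hits",
    "census",
]

MARKER_SET_SIZE = 107


@dataclass(frozen=True)
class MarkerProfile:
    """Per-bin census of the single-copy marker universe."""

    bin_label: str
    copy_count: Mapping[str, int]
    universe_size: int = MARKER_SET_SIZE

    @property
    def completeness(self) -> float:
        """Percent of the marker universe present at least once."""
        present = sum(1 for c in self.copy_count.values() if c >= 1)
        return 100.0 * present / self.universe_size

    @property
    def contamination(self) -> float:
        """Percent of excess marker copies beyond single-copy expectation."""
        extras = sum(max(0, c - 1) for c in self.copy_count.values())
        return 100.0 * extras / self.universe_size


def load_marker_universe(path: str | Path) -> list[str]:
    """Read a marker-id list, one id per line; '#' lines are comments."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if len(set(ids)) != len(ids):
        raise ValueError("marker universe contains duplicate ids")
    return ids


def default_marker_universe() -> list[str]:
    """The bundled synthetic stand-in universe of 107 marker ids."""
    ref = resources.files("microbin.data") / "marker_universe_synthetic107.txt"
    with resources.as_file(ref) as path:
        universe = load_marker_universe(path)
    assert len(universe) == MARKER_SET_SIZE
    return universe


def read_marker_hits(path: str | Path) -> pd.DataFrame:
    """Read a marker-hit TSV: scaffold_id <TAB> marker_id <TAB> gene_id."""
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["scaffold_id", "marker_id", "gene_id"], dtype=str,
    )


def census(
    bin_label: str,
    bin_scaffold_ids: Iterable[str],
    marker_hits: pd.DataFrame,
    universe: list[str] | None = None,
) -> MarkerProfile:
    """Census the marker hits falling on a bin's scaffolds.

    ``copy_count[m]`` is the number of marker-``m`` hit rows on scaffolds
    of the bin (a marker fragmented over two scaffolds counts twice: we
    count hit rows). A hit whose marker id is outside the configured
    universe is an error.
    """
    if universe is None:
        universe = default_marker_universe()
    members = set(bin_scaffold_ids)
    counts = {m: 0 for m in universe}
    hits = marker_hits[marker_hits["scaffold_id"].isin(members)]
    for marker_id in hits["marker_id"]:
        if marker_id not in counts:
            raise KeyError(
                f"marker id {marker_id!r} not in the configured "
                f"{len(universe)}-marker universe"
            )
        counts[marker_id] += 1
    return MarkerProfile(bin_label, counts, universe_size=len(universe))
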
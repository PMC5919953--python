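"""Genome binning in (GC, log10 coverage) space with marker-guided rescue.

Scaffolds from one genome share a compositional signature (GC) and a
depth signature (coverage), so they form clouds in the
(GC, log10 coverage) plane. The original visual protocol drew bin
boundaries by hand around those clouds; here the default realization is
density-based clustering (DBSCAN) on standardized axes, with an optional
user-supplied polygon file for faithful hand-guided operation.

After clustering, unassigned fragments that carry at least one essential
single-copy marker gene are *rescued*: each is attached to the nearest
bin centroid, but only if it lies within a per-sample distance
threshold in standardized space — distant marker fragments stay
unassigned rather than being pulled in indiscriminately. Non-marker
fragments are never rescued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .assembly import Scaffold

__all__ = [
    "UNASSIGNED",
    "BinningParams",
    "ProjectedPoints",
    "BinAssignment",
    "project",
    "cluster",
    "rescue_marker_fragments",
    "read_polygons",
]

UNASSIGNED = "UNASSIGNED"
CLUSTERED = "CLUSTERED"
RESCUED = "RESCUED"

# smallest meaningful axis scales: 1 GC point, 0.05 log10-coverage units.
# Tighter spreads are not stretched to unit variance, so a near-degenerate
# axis (single genome, or identical points) stays compact instead of being
# inflated into apparent structure.
_SCALE_FLOOR = (0.01, 0.05)


@dataclass(frozen=True)
class BinningParams:
    """Knobs of the clustering and rescue stages.

    ``eps``/``min_samples`` parameterize DBSCAN reachability on the
    standardized plane; ``min_cluster_size`` is the smallest scaffold
    count a density cluster needs to become a bin;
    ``rescue_distance_threshold`` is the per-sample cutoff (standardized
    Euclidean units) for attaching unassigned marker fragments.
    """

    eps: float = 0.3
    min_samples: int = 5
    min_cluster_size: int = 5
    rescue_distance_threshold: float = 2.0

    def __post_init__(self) -> None:
        for name in ("eps", "min_samples", "min_cluster_size",
                     "rescue_distance_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ProjectedPoints:
    """Standardized (GC, log10 coverage) coordinates with length weights."""

    scaffold_ids: tuple[str, ...]
    coords: np.ndarray          # (n, 2) standardized
    raw: np.ndarray             # (n, 2) un-standardized (gc, log10 cov)
    weights: np.ndarray         # density weights, ceil(log10 length), >= 1
    lengths: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class BinAssignment:
    """Partition of scaffolds into bins plus an unassigned pool."""

    bin_of: dict[str, str]          # scaffold_id -> bin label or UNASSIGNED
    provenance: dict[str, str]      # scaffold_id -> CLUSTERED/RESCUED/UNASSIGNED

    @property
    def bins(self) -> list[str]:
        return sorted({b for b in self.bin_of.values() if b != UNASSIGNED})

    def members(self, bin_label: str) -> list[str]:
        return sorted(s for s, b in self.bin_of.items() if b == bin_label)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, self.bin_of[s], self.provenance[s]) for s in sorted(self.bin_of)]
        return pd.DataFrame(rows, columns=["scaffold_id", "bin", "provenance"])


def project(scaffolds: Sequence[Scaffold]) -> ProjectedPoints:
    """Map scaffolds to standardized (GC, log10 coverage) points.

    Axes are centered and scaled to unit variance, except that each
    axis's scale is floored (1 GC point, 0.05 log10-coverage units): a
    near-degenerate axis — identical points, or a single genome's tight
    cloud — degenerates toward zeros instead of being inflated into
    apparent structure.
    """
    if not scaffolds:
        raise ValueError("no scaffolds to project")
    for s in scaffolds:
        if s.coverage <= 0:
            raise ValueError(
                f"scaffold {s.scaffold_id!r} has coverage {s.coverage} <= 0; "
                "binning expects coverage-filtered input"
            )
    raw = np.array([[s.gc, math.log10(s.coverage)] for s in scaffolds])
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    scale = np.maximum(std, _SCALE_FLOOR)
    lengths = np.array([s.length for s in scaffolds], dtype=np.int64)
    weights = np.maximum(1, np.ceil(np.log10(np.maximum(lengths, 2))).astype(int))
    return ProjectedPoints(
        scaffold_ids=tuple(s.scaffold_id for s in scaffolds),
        coords=(raw - mean) / scale,
        raw=raw,
        weights=weights,
        lengths=lengths,
        mean=mean,
        scale=scale,
    )


def _relabel(points: ProjectedPoints, labels: np.ndarray,
             min_cluster_size: int) -> BinAssignment:
    """Turn raw cluster labels into bin01.. ordered by total length."""
    sizes: dict[int, int] = {}
    masses: dict[int, int] = {}
    for lab, length in zip(labels, points.lengths):
        if lab < 0:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        masses[lab] = masses.get(lab, 0) + int(length)
    kept = [lab for lab, n in sizes.items() if n >= min_cluster_size]
    # dominant genome first; total length then label for determinism
    kept.sort(key=lambda lab: (-masses[lab], lab))
    name_of = {lab: f"bin{i + 1:02d}" for i, lab in enumerate(kept)}
    bin_of, prov = {}, {}
    for sid, lab in zip(points.scaffold_ids, labels):
        if lab in name_of:
            bin_of[sid] = name_of[lab]
            prov[sid] = CLUSTERED
        else:
            bin_of[sid] = UNASSIGNED
            prov[sid] = UNASSIGNED
    return BinAssignment(bin_of, prov)


def cluster(
    points: ProjectedPoints,
    params: BinningParams = BinningParams(),
    polygons: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> BinAssignment:
    """Group projected scaffolds into provisional bins.

    Default: DBSCAN on the standardized plane, with per-point density
    weights proportional to log10 scaffold length so long scaffolds
    anchor clusters (their visual prominence in a scatter plot). Density
    clusters smaller than ``min_cluster_size`` scaffolds are dissolved
    into the unassigned pool.

    If ``polygons`` is given (bin label -> vertex list in *raw*
    (gc, log10 coverage) coordinates), membership is decided by
    point-in-polygon instead — the hand-drawn-boundary mode.
    """
    if polygons is not None:
        return _cluster_by_polygons(points, polygons, params)
    db = DBSCAN(eps=params.eps, min_samples=params.min_samples)
    labels = db.fit_predict(points.coords, sample_weight=points.weights)
    return _relabel(points, labels, params.min_cluster_size)


def _point_in_polygon(x: float, y: float,
                      verts: Sequence[tuple[float, float]]) -> bool:
    # ray casting; boundary points count as inside
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x <= xint:
                inside = not inside
    return inside


def _cluster_by_polygons(points, polygons, params) -> BinAssignment:
    labels = np.full(len(points.scaffold_ids), -1)
    poly_names = sorted(polygons)
    for sid_idx in range(len(points.scaffold_ids)):
        x, y = points.raw[sid_idx]
        for p_idx, name in enumerate(poly_names):
            if _point_in_polygon(x, y, polygons[name]):
                labels[sid_idx] = p_idx
                break
    assignment = _relabel(points, labels, min_cluster_size=1)
    # keep the user's polygon names
    rename = {}
    for p_idx, name in enumerate(poly_names):
        mask = labels == p_idx
        if mask.any():
            sid = points.scaffold_ids[int(np.argmax(mask))]
            rename[assignment.bin_of[sid]] = name
    bin_of = {s: rename.get(b, b) for s, b in assignment.bin_of.items()}
    return BinAssignment(bin_of, assignment.provenance)


def read_polygons(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a polygon file: bin_label <TAB> gc <TAB> log10_cov per vertex row."""
    polygons: dict[str, list[tuple[float, float]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, gc, logcov = line.split("\t")
        polygons.setdefault(name, []).append((float(gc), float(logcov)))
    return polygons


def rescue_marker_fragments(
    assignment: BinAssignment,
    points: ProjectedPoints,
    marker_hits: pd.DataFrame,
    params: BinningParams = BinningParams(),
) -> BinAssignment:
    """Attach unassigned marker-bearing fragments to nearby bins.

    An unassigned scaffold carrying >= 1 essential single-copy gene is
    attached to its nearest bin centroid in standardized space iff the
    distance is <= ``rescue_distance_threshold``; beyond the threshold it
    stays unassigned (the deliberate restraint versus rescuing every
    marker fragment). Scaffolds without markers are never rescued, bins
    are never created or emptied by rescue.
    """
    known = set(points.scaffold_ids)
    for sid in marker_hits["scaffold_id"]:
        if sid not in known:
            raise KeyError(f"marker hit references unknown scaffold {sid!r}")
    idx_of = {sid: i for i, sid in enumerate(points.scaffold_ids)}
    bins = assignment.bins
    if not bins:
        return assignment
    centroids = {}
    sizes = {}
    for b in bins:
        members = assignment.members(b)
        centroids[b] = points.coords[[idx_of[s] for s in members]].mean(axis=0)
        sizes[b] = len(members)
    marker_scaffolds = set(marker_hits["scaffold_id"])
    bin_of = dict(assignment.bin_of)
    prov = dict(assignment.provenance)
    for sid, b in assignment.bin_of.items():
        if b != UNASSIGNED or sid not in marker_scaffolds:
            continue
        p = points.coords[idx_of[sid]]
        dists = {lab: float(np.linalg.norm(p - c)) for lab, c in centroids.items()}
        dmin = min(dists.values())
        if dmin > params.rescue_distance_threshold:
            continue
        # ties: larger bin first, then lexicographically smallest label
        tied = [lab for lab, d in dists.items() if d <= dmin + 1e-12]
        tied.sort(key=lambda lab: (-sizes[lab], lab))
        bin_of[sid] = tied[0]
        prov[sid] = RESCUED
    return BinAssignment(bin_of, prov)
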
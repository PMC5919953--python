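"""Pipeline configuration: one YAML file, every stage parameter in one place.

Defaults are the study constants where a constant exists (scaffold
filters, hit filters, the 65% consistency threshold, the 107-marker
universe, the quality rubric); everything else is a package design
choice. ``PARAM_PROVENANCE`` tags each parameter accordingly so run
logs can show which is which.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "PARAM_PROVENANCE", "load_config"]

PARAM_PROVENANCE = {
    "scaffolds_fasta": "input",
    "coverage_tsv": "input",
    "marker_hits_tsv": "input",
    "gene_hits_tsv": "input",
    "proteome_dir": "input",
    "marker_list": "input",
    "polygon_file": "input",
    "sample_id": "input",
    "outdir": "input",
    "min_length": "paper-constant",
    "min_coverage": "paper-constant",
    "max_evalue": "paper-constant",
    "min_identity": "paper-constant",
    "min_query_coverage": "paper-constant",
    "max_hits_per_gene": "paper-constant",
    "consistency_threshold": "paper-constant",
    "eps": "decision",
    "min_samples": "decision",
    "min_cluster_size": "decision",
    "rescue_distance_threshold": "decision",
    "vote_method": "decision",
    "include_unassigned": "decision",
    "cv_k": "decision",
    "seed": "decision",
}


@dataclass(frozen=True)
class PipelineConfig:
    # inputs
    scaffolds_fasta: str = ""
    coverage_tsv: str = ""
    marker_hits_tsv: str = ""
    gene_hits_tsv: str = ""
    proteome_dir: str | None = None     # dir of <genome>.faa; tree stage skipped if unset
    marker_list: str | None = None      # defaults to the bundled 107-id universe
    polygon_file: str | None = None     # hand-drawn bin boundaries, optional
    sample_id: str = "sample"
    outdir: str = "run"
    # scaffold filter
    min_length: int = 200
    min_coverage: float = 3.0
    # binning
    eps: float = 0.3
    min_samples: int = 5
    min_cluster_size: int = 5
    rescue_distance_threshold: float = 2.0
    # taxonomy
    max_evalue: float = 1e-5
    min_identity: float = 60.0
    min_query_coverage: float = 50.0
    max_hits_per_gene: int = 100
    consistency_threshold: float = 65.0
    vote_method: str = "best_hit"
    # report
    include_unassigned: bool = False
    # phylogeny
    cv_k: int = 6
    # reproducibility
    seed: int = 0

    def validate(self) -> list[str]:
        """Pure check; returns the list of violations (empty = ok)."""
        v: list[str] = []
        for name in ("scaffolds_fasta", "coverage_tsv", "marker_hits_tsv",
                     "gene_hits_tsv"):
            path = getattr(self, name)
            if not path:
                v.append(f"{name} is required")
            elif not Path(path).exists():
                v.append(f"{name}: no such file {path!r}")
        for name, p in (("marker_list", self.marker_list),
                        ("polygon_file", self.polygon_file),
                        ("proteome_dir", self.proteome_dir)):
            if p is not None and not Path(p).exists():
                v.append(f"{name}: no such path {p!r}")
        if self.min_length < 0:
            v.append("min_length must be >= 0")
        if self.min_coverage < 0:
            v.append("min_coverage must be >= 0")
        for name in ("eps", "min_samples", "min_cluster_size",
                     "rescue_distance_threshold"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be positive")
        if self.max_evalue <= 0:
            v.append("max_evalue must be positive")
        if not 0 <= self.min_identity <= 100:
            v.append("min_identity must lie in [0, 100]")
        if not 0 <= self.min_query_coverage <= 100:
            v.append("min_query_coverage must lie in [0, 100]")
        if not 1 <= self.max_hits_per_gene <= 10_000:
            v.append("max_hits_per_gene must lie in [1, 10000]")
        if not 0 < self.consistency_threshold < 100:
            v.append("consistency_threshold must lie in (0, 100)")
        if self.vote_method not in ("best_hit", "fractional"):
            v.append("vote_method must be 'best_hit' or 'fractional'")
        if not 3 <= self.cv_k <= 8:
            v.append("cv_k must lie in [3, 8]")
        return v

    def with_overrides(self, overrides: dict[str, str]) -> "PipelineConfig":
        """Apply --set key=value overrides, coercing to field types."""
        typed: dict[str, object] = {}
        by_name = {f.name: f for f in fields(self)}
        for key, raw in overrides.items():
            if key not in by_name:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(self, key)
            if isinstance(current, bool):
                typed[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                typed[key] = int(raw)
            elif isinstance(current, float):
                typed[key] = float(raw)
            else:
                typed[key] = raw
        return replace(self, **typed)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
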
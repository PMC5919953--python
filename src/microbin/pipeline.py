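"""End-to-end orchestration: filter -> bin -> markers -> taxon -> rate -> report -> tree.

Each stage is a standalone function reading and writing plain-text files
under the run directory, so running the stages one at a time reproduces
``run_pipeline`` byte for byte. Every run writes a parameter log tagging
each value as a study constant or a package decision, and a
machine-readable ``summary.json`` at the run root. Given the same config
and seed, outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import assembly, binning, markers, quality, taxonomy, cvtree
from .config import PipelineConfig, PARAM_PROVENANCE

__all__ = [
    "PipelineError",
    "run_pipeline",
    "stage_filter",
    "stage_bin",
    "stage_markers",
    "stage_taxon",
    "stage_rate",
    "stage_report",
    "stage_cvtree",
]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _binning_params(config: PipelineConfig) -> binning.BinningParams:
    return binning.BinningParams(
        eps=config.eps,
        min_samples=config.min_samples,
        min_cluster_size=config.min_cluster_size,
        rescue_distance_threshold=config.rescue_distance_threshold,
    )


def _load_filtered(config: PipelineConfig) -> list[assembly.Scaffold]:
    out = _outdir(config)
    return assembly.read_scaffolds(
        out / "filtered.fasta", out / "filtered_coverage.tsv", config.sample_id
    )


def stage_filter(config: PipelineConfig) -> None:
    """Apply the length/coverage filter; write filtered FASTA + stats."""
    out = _outdir(config)
    scaffolds = assembly.read_scaffolds(
        config.scaffolds_fasta, config.coverage_tsv, config.sample_id
    )
    kept = assembly.filter_scaffolds(
        scaffolds, config.min_length, config.min_coverage
    )
    assembly.write_scaffolds(kept, out / "filtered.fasta",
                             out / "filtered_coverage.tsv")
    with open(out / "assembly_summary.tsv", "w") as fh:
        fh.write("stage\tn_scaffolds\ttotal_length\tn50\tmean_gc\tmax_length\n")
        for name, group in (("raw", scaffolds), ("filtered", kept)):
            if group:
                s = assembly.summarize_assembly(group)
                fh.write(f"{name}\t{s.n_scaffolds}\t{s.total_length}\t{s.n50}"
                         f"\t{s.mean_gc:.4f}\t{s.max_length}\n")
            else:
                fh.write(f"{name}\t0\t0\t0\tNA\t0\n")


def stage_bin(config: PipelineConfig) -> None:
    """Cluster filtered scaffolds and rescue marker-bearing fragments."""
    out = _outdir(config)
    scaffolds = _load_filtered(config)
    if not scaffolds:
        raise PipelineError("bin", "no scaffolds left after filtering; "
                                   "check min_length/min_coverage")
    points = binning.project(scaffolds)
    polygons = (binning.read_polygons(config.polygon_file)
                if config.polygon_file else None)
    params = _binning_params(config)
    provisional = binning.cluster(points, params, polygons=polygons)
    marker_hits = markers.read_marker_hits(config.marker_hits_tsv)
    marker_hits = marker_hits[marker_hits["scaffold_id"].isin(points.scaffold_ids)]
    final = binning.rescue_marker_fragments(provisional, points, marker_hits, params)
    final.to_frame().to_csv(out / "bins.tsv", sep="\t", index=False)
    scatter = pd.DataFrame({
        "scaffold_id": points.scaffold_ids,
        "gc": points.raw[:, 0].round(4),
        "log10_coverage": points.raw[:, 1].round(4),
        "length": points.lengths,
        "bin": [final.bin_of[s] for s in points.scaffold_ids],
    })
    scatter.to_csv(out / "scatter.tsv", sep="\t", index=False)


def _load_assignment(config: PipelineConfig) -> binning.BinAssignment:
    out = _outdir(config)
    df = pd.read_csv(out / "bins.tsv", sep="\t", dtype=str)
    return binning.BinAssignment(
        bin_of=dict(zip(df["scaffold_id"], df["bin"])),
        provenance=dict(zip(df["scaffold_id"], df["provenance"])),
    )


def stage_markers(config: PipelineConfig) -> None:
    """Census the 107-marker universe per bin; write completeness table."""
    out = _outdir(config)
    assignment = _load_assignment(config)
    universe = (markers.load_marker_universe(config.marker_list)
                if config.marker_list else markers.default_marker_universe())
    marker_hits = markers.read_marker_hits(config.marker_hits_tsv)
    rows = []
    for b in assignment.bins:
        profile = markers.census(b, assignment.members(b), marker_hits, universe)
        rows.append((b, f"{profile.completeness:.2f}",
                     f"{profile.contamination:.2f}"))
    with open(out / "marker_profiles.tsv", "w") as fh:
        fh.write("bin\tcompleteness\tcontamination\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def stage_taxon(config: PipelineConfig) -> None:
    """Vote each bin into a taxon; write assignment + consistency table."""
    out = _outdir(config)
    assignment = _load_assignment(config)
    hits = taxonomy.read_gene_hits(config.gene_hits_tsv)
    params = taxonomy.HitFilterParams(
        max_evalue=config.max_evalue,
        min_identity=config.min_identity,
        min_query_coverage=config.min_query_coverage,
        max_hits_per_gene=config.max_hits_per_gene,
    )
    retained = taxonomy.filter_hits(hits, params)
    retained = retained.assign(
        scaffold_id=[taxonomy.scaffold_of_gene(g) for g in retained["qseqid"]]
    )
    with open(out / "taxon_assignments.tsv", "w") as fh:
        fh.write("bin\trank\ttaxon\tconsistency\tn_assigned_genes\n")
        for b in assignment.bins:
            members = set(assignment.members(b))
            bin_hits = retained[retained["scaffold_id"].isin(members)]
            t = taxonomy.assign_bin(b, bin_hits, method=config.vote_method,
                                    threshold=config.consistency_threshold)
            fh.write(f"{b}\t{t.rank.value}\t{t.taxon or 'Unclassified'}"
                     f"\t{t.consistency:.2f}\t{t.n_assigned_genes}\n")


def stage_rate(config: PipelineConfig) -> None:
    """Apply the five-tier rubric; write per-bin ratings."""
    out = _outdir(config)
    assignment = _load_assignment(config)
    profiles = pd.read_csv(out / "marker_profiles.tsv", sep="\t", index_col="bin")
    taxa = pd.read_csv(out / "taxon_assignments.tsv", sep="\t", index_col="bin")
    with open(out / "ratings.tsv", "w") as fh:
        fh.write("bin\tcategory\tstars\trule\n")
        for b in assignment.bins:
            if b not in profiles.index or b not in taxa.index:
                raise PipelineError("rate", f"missing upstream rows for bin {b!r}")
            r = quality.rate_bin(
                float(profiles.loc[b, "completeness"]),
                float(profiles.loc[b, "contamination"]),
                float(taxa.loc[b, "consistency"]),
                len(assignment.members(b)),
            )
            fh.write(f"{b}\t{r.category.name}\t{r.stars}\t{r.criteria_trace}\n")


def stage_report(config: PipelineConfig) -> None:
    """Assemble the community table and a JSON twin."""
    out = _outdir(config)
    scaffolds = _load_filtered(config)
    assignment = _load_assignment(config)
    universe = (markers.load_marker_universe(config.marker_list)
                if config.marker_list else markers.default_marker_universe())
    marker_hits = markers.read_marker_hits(config.marker_hits_tsv)
    profiles = {b: markers.census(b, assignment.members(b), marker_hits, universe)
                for b in assignment.bins}
    taxa_df = pd.read_csv(out / "taxon_assignments.tsv", sep="\t", index_col="bin")
    ratings_df = pd.read_csv(out / "ratings.tsv", sep="\t", index_col="bin")
    taxa = {
        b: taxonomy.TaxonAssignment(
            b, taxonomy.Rank(taxa_df.loc[b, "rank"]),
            None if taxa_df.loc[b, "taxon"] == "Unclassified"
            else str(taxa_df.loc[b, "taxon"]),
            float(taxa_df.loc[b, "consistency"]),
            int(taxa_df.loc[b, "n_assigned_genes"]),
        )
        for b in assignment.bins
    }
    ratings = {
        b: quality.QualityRating(
            quality.QualityCategory[str(ratings_df.loc[b, "category"])],
            str(ratings_df.loc[b, "rule"]),
        )
        for b in assignment.bins
    }
    abundances = quality.relative_abundance(
        assignment, scaffolds, include_unassigned=config.include_unassigned
    )
    report = quality.community_report(
        assignment, scaffolds, profiles, taxa, ratings, abundances,
        sample_id=config.sample_id,
    )
    report.to_csv(out / "community_report.tsv", sep="\t", index=False)
    records = report.to_dict(orient="records")
    (out / "report.json").write_text(json.dumps(records, indent=1) + "\n")


def stage_cvtree(config: PipelineConfig) -> None:
    """Composition-vector distances + NJ tree over the proteome directory."""
    out = _outdir(config)
    if not config.proteome_dir:
        return
    faa_paths = sorted(Path(config.proteome_dir).glob("*.faa"))
    if len(faa_paths) < 3:
        raise PipelineError(
            "cvtree", f"need >= 3 proteome FASTA files in {config.proteome_dir!r}, "
                      f"found {len(faa_paths)}"
        )
    vectors = [
        cvtree.composition_vector(p.stem, cvtree.read_proteome(p), k=config.cv_k)
        for p in faa_paths
    ]
    labels, matrix = cvtree.distance_matrix(vectors)
    cvtree.write_phylip(labels, matrix, out / "cv_distances.phylip")
    tree = cvtree.neighbor_joining(labels, matrix)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")


_STAGES = [
    ("filter", stage_filter),
    ("bin", stage_bin),
    ("markers", stage_markers),
    ("taxon", stage_taxon),
    ("rate", stage_rate),
    ("report", stage_report),
    ("cvtree", stage_cvtree),
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the run directory.

    Validates the config first, logs effective parameters with their
    provenance tags, wraps any stage failure in a :class:`PipelineError`
    naming the stage, and finishes with ``summary.json``.
    """
    violations = config.validate()
    if violations:
        raise PipelineError("config", "; ".join(violations))
    out = _outdir(config)
    log_lines = ["# microbin run log", "# parameter = value  [provenance]"]
    for name, tag in PARAM_PROVENANCE.items():
        log_lines.append(f"param {name} = {getattr(config, name)!r}  [{tag}]")
    for name, fn in _STAGES:
        try:
            fn(config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        if name == "cvtree" and not config.proteome_dir:
            log_lines.append("stage cvtree: skipped (no proteome_dir configured)")
        else:
            log_lines.append(f"stage {name}: ok")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    report = pd.read_csv(out / "community_report.tsv", sep="\t")
    bins = report[report["Genome Bin ID"] != "TOTAL"]
    summary = {
        "sample_id": config.sample_id,
        "n_bins": int(len(bins)),
        "total_binned_mb": float(bins["Genome Bin Size (Mb)"].sum().round(2)),
        "ratings": {
            stars: int((bins["Quality rating"] == stars).sum())
            for stars in sorted(bins["Quality rating"].unique())
        },
        "tree_written": (out / "tree.nwk").exists(),
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return out
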
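"""Shared fixtures: small synthetic communities and pipeline run dirs."""

from __future__ import annotations

from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True)
_hyp_settings.load_profile("repro")

from pathlib import Path

import pytest

from microbin.config import PipelineConfig
from microbin.markers import default_marker_universe
from microbin.synthetic import (
    CommunitySpec,
    GenomeSpec,
    generate_community,
    synthetic_proteomes,
)

LINEAGES = {
    "Microcystis_dom": ("Microcystis aeruginosa", "Microcystis", "Microcystaceae",
                        "Chroococcales", "Oscillatoriophycideae", "Cyanobacteria"),
    "Brevundimonas_e1": ("Brevundimonas sp.", "Brevundimonas", "Caulobacteraceae",
                         "Caulobacterales", "Alphaproteobacteria", "Proteobacteria"),
    "Flavobacterium_e2": ("Flavobacterium sp.", "Flavobacterium", "Flavobacteriaceae",
                          "Flavobacteriales", "Flavobacteriia", "Bacteroidetes"),
}


def three_genome_spec(seed: int = 11, label_noise: float = 0.0) -> CommunitySpec:
    """Dominant high-coverage genome plus two well-separated epibionts."""
    universe = default_marker_universe()
    single = {m: 1 for m in universe}
    genomes = (
        GenomeSpec("Microcystis_dom", LINEAGES["Microcystis_dom"],
                   gc_target=0.43, coverage_mean=200.0, coverage_cv=0.12,
                   genome_length=120_000, n_scaffolds=12,
                   marker_copy_numbers=single),
        GenomeSpec("Brevundimonas_e1", LINEAGES["Brevundimonas_e1"],
                   gc_target=0.68, coverage_mean=40.0, coverage_cv=0.12,
                   genome_length=80_000, n_scaffolds=10,
                   marker_copy_numbers=single),
        GenomeSpec("Flavobacterium_e2", LINEAGES["Flavobacterium_e2"],
                   gc_target=0.32, coverage_mean=12.0, coverage_cv=0.12,
                   genome_length=80_000, n_scaffolds=10,
                   marker_copy_numbers=single),
    )
    return CommunitySpec(genomes=genomes, label_noise=label_noise,
                         hit_redundancy=4, seed=seed)


@pytest.fixture(scope="session")
def small_community():
    return generate_community(three_genome_spec(), separable=True)


@pytest.fixture()
def community_dir(tmp_path: Path, small_community):
    """The 3-genome community written out, with proteomes, ready for a run."""
    data = tmp_path / "data"
    small_community.write(data)
    faa_dir = data / "proteomes"
    faa_dir.mkdir()
    proteomes = synthetic_proteomes(small_community.spec, seed=99,
                                    proteins_per_genome=40, protein_length=150)
    for genome_id, seqs in proteomes.items():
        with open(faa_dir / f"{genome_id}.faa", "w") as fh:
            for pid, seq in seqs:
                fh.write(f">{pid}\n{seq}\n")
    return data


def make_config(data_dir: Path, outdir: Path, **overrides) -> PipelineConfig:
    base = dict(
        scaffolds_fasta=str(data_dir / "scaffolds.fasta"),
        coverage_tsv=str(data_dir / "coverage.tsv"),
        marker_hits_tsv=str(data_dir / "marker_hits.tsv"),
        gene_hits_tsv=str(data_dir / "gene_hits.tsv"),
        proteome_dir=str(data_dir / "proteomes"),
        sample_id="SY01",
        outdir=str(outdir),
        min_samples=4,
        min_cluster_size=4,
    )
    base.update(overrides)
    return PipelineConfig(**base)
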
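"""Synthetic colony-community generator with known ground truth.

Emulates the inputs of a genome-resolved metagenome study of
cyanobacterial colonies: one dominant *Microcystis*-like genome (~43%
GC, high coverage, 36-65% of community sequence mass) plus a set of
epibiont genomes with distinct (GC, coverage) signatures. The generator
emits assembled scaffolds (FASTA), a per-scaffold coverage table,
a single-copy marker-hit table over a 107-marker universe, and a
taxon-labeled protein-hit table in BLAST outfmt-6 dialect with lineage
columns — together with complete ground-truth maps, so every
downstream stage is testable without external data.

Sequence composition is i.i.d. nucleotides at the target GC (downstream
stages use only GC, length, coverage, and labels); per-scaffold depth is
gamma-distributed around the genome mean with a stated coefficient of
variation. Reads, assembly errors, chimeras, and protein evolution are
deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assembly import Scaffold, write_scaffolds
from .markers import MARKER_SET_SIZE, default_marker_universe

__all__ = [
    "RANKS",
    "GenomeSpec",
    "CommunitySpec",
    "GroundTruth",
    "SyntheticCommunity",
    "fragment_genome",
    "generate_community",
    "example_community",
    "synthetic_proteomes",
    "OUTFMT6_COLUMNS",
    "LINEAGE_COLUMNS",
    "GENE_HIT_COLUMNS",
]

RANKS = ("species", "genus", "family", "order", "class", "phylum")

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)
LINEAGE_COLUMNS = RANKS
GENE_HIT_COLUMNS = OUTFMT6_COLUMNS + LINEAGE_COLUMNS

MIN_SCAFFOLD_LEN = 200


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic genome.

    ``marker_copy_numbers`` maps marker ids from the 107-member universe
    to copy counts; unlisted markers are absent (copy 0). ``gene_density``
    is protein-coding genes per kbp (~1 for bacteria).
    """

    genome_id: str
    taxon_lineage: tuple[str, str, str, str, str, str]
    gc_target: float
    coverage_mean: float
    genome_length: int
    n_scaffolds: int
    coverage_cv: float = 0.2
    marker_copy_numbers: Mapping[str, int] = field(default_factory=dict)
    gene_density: float = 1.0

    def __post_init__(self) -> None:
        if not 0.2 <= self.gc_target <= 0.8:
            raise ValueError(f"gc_target must lie in [0.2, 0.8], got {self.gc_target}")
        if self.coverage_mean < 0 or self.coverage_cv < 0:
            raise ValueError("coverage_mean and coverage_cv must be >= 0")
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if self.genome_length < self.n_scaffolds * MIN_SCAFFOLD_LEN:
            raise ValueError(
                f"genome_length {self.genome_length} cannot be split into "
                f"{self.n_scaffolds} scaffolds of >= {MIN_SCAFFOLD_LEN} bp"
            )
        if len(self.taxon_lineage) != len(RANKS):
            raise ValueError(f"taxon_lineage needs {len(RANKS)} ranks {RANKS}")
        if any(c < 0 for c in self.marker_copy_numbers.values()):
            raise ValueError("marker copy numbers must be >= 0")


@dataclass(frozen=True)
class CommunitySpec:
    """A community of genomes plus emission parameters for the hit tables.

    ``label_noise`` is the fraction of genes whose best-hit lineage is
    replaced with a random other genome's lineage; ``hit_redundancy`` is
    the number of hit rows emitted per gene (<= 100, the search cap).
    """

    genomes: tuple[GenomeSpec, ...]
    label_noise: float = 0.0
    hit_redundancy: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genomes) < 2:
            raise ValueError("a community needs at least 2 genomes")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if not 1 <= self.hit_redundancy <= 100:
            raise ValueError("hit_redundancy must lie in [1, 100]")
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("genome ids must be unique")


@dataclass(frozen=True)
class GroundTruth:
    scaffold_to_genome: dict[str, str]
    gene_to_genome: dict[str, str]
    marker_placements: list[tuple[str, str]]


@dataclass(frozen=True)
class SyntheticCommunity:
    """Everything one generator run emits, plus its ground truth."""

    spec: CommunitySpec
    scaffolds: list[Scaffold]
    coverage: pd.DataFrame      # scaffold_id, mean_depth
    marker_hits: pd.DataFrame   # scaffold_id, marker_id, gene_id
    gene_hits: pd.DataFrame     # outfmt-6 columns + lineage columns
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables under ``outdir``; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scaffolds": outdir / "scaffolds.fasta",
            "coverage": outdir / "coverage.tsv",
            "marker_hits": outdir / "marker_hits.tsv",
            "gene_hits": outdir / "gene_hits.tsv",
            "truth_scaffolds": outdir / "truth_scaffolds.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "spec": outdir / "community_spec.yaml",
        }
        write_scaffolds(self.scaffolds, paths["scaffolds"], paths["coverage"])
        self.marker_hits.to_csv(paths["marker_hits"], sep="\t", header=False, index=False)
        self.gene_hits.to_csv(
            paths["gene_hits"], sep="\t", header=False, index=False,
            float_format="%.6g",
        )
        pd.DataFrame(
            sorted(self.truth.scaffold_to_genome.items()),
            columns=["scaffold_id", "genome_id"],
        ).to_csv(paths["truth_scaffolds"], sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.gene_to_genome.items()),
            columns=["gene_id", "genome_id"],
        ).to_csv(paths["truth_genes"], sep="\t", index=False)
        spec_dict = asdict(self.spec)
        for g in spec_dict["genomes"]:
            g["marker_copy_numbers"] = dict(g["marker_copy_numbers"])
            g["taxon_lineage"] = list(g["taxon_lineage"])
        spec_dict["genomes"] = list(spec_dict["genomes"])
        paths["spec"].write_text(yaml.safe_dump(spec_dict, sort_keys=True))
        return paths


def fragment_genome(genome: GenomeSpec, seed: int | np.random.Generator) -> list[int]:
    """Split ``genome_length`` into ``n_scaffolds`` lengths, each >= 200 bp.

    Each scaffold gets the 200 bp floor; the remainder is apportioned by
    Dirichlet weights, with rounding leftovers given to the first
    scaffolds. Lengths sum to ``genome_length`` exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genome.n_scaffolds
    extra = genome.genome_length - n * MIN_SCAFFOLD_LEN
    if extra < 0:  # unreachable through GenomeSpec, kept for direct calls
        raise ValueError("infeasible length partition")
    if n == 1:
        return [genome.genome_length]
    weights = rng.dirichlet(np.ones(n))
    alloc = np.floor(weights * extra).astype(np.int64)
    leftover = extra - int(alloc.sum())
    alloc[:leftover] += 1
    lengths = (alloc + MIN_SCAFFOLD_LEN).tolist()
    assert sum(lengths) == genome.genome_length
    return [int(x) for x in lengths]


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. nucleotide string with an exact (rounded) GC base count."""
    n_gc = int(round(gc * length))
    n_at = length - n_gc
    bases = np.empty(length, dtype="S1")
    bases[: n_gc - n_gc // 2] = b"G"
    bases[n_gc - n_gc // 2 : n_gc] = b"C"
    bases[n_gc : n_gc + (n_at - n_at // 2)] = b"A"
    bases[n_gc + (n_at - n_at // 2) :] = b"T"
    return rng.permutation(bases).tobytes().decode("ascii")


def _check_separable(
    genomes: Sequence[GenomeSpec], gc_tol: float, logcov_tol: float
) -> None:
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            d_gc = abs(a.gc_target - b.gc_target)
            d_cov = abs(
                np.log10(max(a.coverage_mean, 0.01))
                - np.log10(max(b.coverage_mean, 0.01))
            )
            if d_gc < gc_tol and d_cov < logcov_tol:
                raise ValueError(
                    f"genomes {a.genome_id!r} and {b.genome_id!r} are not "
                    f"separable: |dGC|={d_gc:.3f} < {gc_tol} and "
                    f"|dlog10cov|={d_cov:.3f} < {logcov_tol}"
                )


def generate_community(
    spec: CommunitySpec,
    separable: bool = False,
    gc_tol: float = 0.03,
    logcov_tol: float = 0.3,
) -> SyntheticCommunity:
    """Realize a :class:`CommunitySpec` into scaffolds, tables, and truth.

    With ``separable=True`` the spec is rejected if any two genomes sit
    within ``gc_tol`` GC units AND ``logcov_tol`` log10-coverage units of
    each other — the certified-separable mode used for binning
    benchmarks. Identical spec + seed gives byte-identical outputs.
    """
    if separable:
        _check_separable(spec.genomes, gc_tol, logcov_tol)
    rng = np.random.default_rng(spec.seed)
    universe = default_marker_universe()
    universe_set = set(universe)
    lineages = {g.genome_id: g.taxon_lineage for g in spec.genomes}
    genome_ids = [g.genome_id for g in spec.genomes]

    scaffolds: list[Scaffold] = []
    marker_rows: list[tuple[str, str, str]] = []
    gene_rows: list[tuple] = []
    scaffold_to_genome: dict[str, str] = {}
    gene_to_genome: dict[str, str] = {}
    marker_placements: list[tuple[str, str]] = []

    for g in spec.genomes:
        for m in g.marker_copy_numbers:
            if m not in universe_set:
                raise KeyError(f"{g.genome_id}: marker id {m!r} outside the universe")
        lengths = fragment_genome(g, rng)
        ids = [f"{g.genome_id}.s{i:03d}" for i in range(1, len(lengths) + 1)]
        if g.coverage_cv > 0:
            shape = 1.0 / g.coverage_cv**2
            covs = rng.gamma(shape, g.coverage_mean / shape, size=len(lengths))
        else:
            covs = np.full(len(lengths), g.coverage_mean)
        covs = np.maximum(covs, 0.01)
        for sid, L, cov in zip(ids, lengths, covs):
            seq = _random_sequence(L, g.gc_target, rng)
            scaffolds.append(Scaffold(sid, seq, float(round(cov, 3)), "synthetic"))
            scaffold_to_genome[sid] = g.genome_id

        weights = np.asarray(lengths, dtype=float)
        weights /= weights.sum()

        # each marker copy lands on exactly one length-weighted scaffold
        gene_counter = 0
        for marker_id in universe:  # universe order keeps output deterministic
            copies = g.marker_copy_numbers.get(marker_id, 0)
            for _ in range(copies):
                sid = ids[rng.choice(len(ids), p=weights)]
                gene_counter += 1
                marker_rows.append((sid, marker_id, f"{sid}_marker{gene_counter}"))
                marker_placements.append((sid, marker_id))

        n_genes = max(1, int(round(g.gene_density * g.genome_length / 1000)))
        orf_index = {sid: 0 for sid in ids}
        other_ids = [x for x in genome_ids if x != g.genome_id]
        for _ in range(n_genes):
            sid = ids[rng.choice(len(ids), p=weights)]
            orf_index[sid] += 1
            gene_id = f"{sid}_{orf_index[sid]}"
            gene_to_genome[gene_id] = g.genome_id
            qlen = int(rng.integers(100, 400))
            noisy = rng.random() < spec.label_noise
            if noisy and other_ids:
                best_lineage = lineages[other_ids[rng.choice(len(other_ids))]]
            else:
                best_lineage = g.taxon_lineage
            base_score = float(rng.uniform(300, 800))
            # best row: full-length, high identity, passes every filter
            gene_rows.append(
                (gene_id, f"ref|{best_lineage[0]}", round(float(rng.uniform(75, 99)), 1),
                 qlen, 0, 0, 1, qlen, 1, qlen,
                 10.0 ** -float(rng.uniform(20, 60)), round(base_score + 50, 1))
                + best_lineage
            )
            for j in range(spec.hit_redundancy - 1):
                lin = lineages[genome_ids[rng.choice(len(genome_ids))]]
                span = max(30, int(rng.uniform(0.3, 1.0) * qlen))
                qstart = int(rng.integers(1, qlen - span + 2))
                gene_rows.append(
                    (gene_id, f"ref|{lin[0]}|{j}", round(float(rng.uniform(40, 95)), 1),
                     span, int(span * 0.1), 0, qstart, qstart + span - 1, 1, span,
                     10.0 ** -float(rng.uniform(3, 20)),
                     round(base_score - 10 * (j + 1), 1))
                    + lin
                )

    coverage = pd.DataFrame(
        [(s.scaffold_id, s.coverage) for s in scaffolds],
        columns=["scaffold_id", "mean_depth"],
    )
    marker_hits = pd.DataFrame(
        marker_rows, columns=["scaffold_id", "marker_id", "gene_id"]
    )
    gene_hits = pd.DataFrame(gene_rows, columns=list(GENE_HIT_COLUMNS))
    return SyntheticCommunity(
        spec=spec,
        scaffolds=scaffolds,
        coverage=coverage,
        marker_hits=marker_hits,
        gene_hits=gene_hits,
        truth=GroundTruth(scaffold_to_genome, gene_to_genome, marker_placements),
    )


# (genus, family, order, class, phylum, GC, coverage) palette for epibionts,
# named after taxa recurrent in cyanobacterial colony communities. GC values
# sit on a 0.03 grid (skipping the dominant genome's 0.43 neighborhood) and
# coverages alternate low/high, so every pair of palette genomes — and each
# against the dominant genome — is well separated in GC or log10 coverage.
_EPIBIONT_PALETTE = [
    ("Flavobacterium", "Flavobacteriaceae", "Flavobacteriales", "Flavobacteriia", "Bacteroidetes", 0.28, 8.0),
    ("Flavihumibacter", "Chitinophagaceae", "Chitinophagales", "Chitinophagia", "Bacteroidetes", 0.31, 120.0),
    ("Gemmatimonas", "Gemmatimonadaceae", "Gemmatimonadales", "Gemmatimonadetes", "Gemmatimonadetes", 0.34, 15.0),
    ("Limnobacter", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria", 0.37, 200.0),
    ("Flectobacillus", "Cytophagaceae", "Cytophagales", "Cytophagia", "Bacteroidetes", 0.40, 10.0),
    ("Acidovorax", "Comamonadaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria", 0.46, 90.0),
    ("Hydrogenophaga", "Comamonadaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria", 0.49, 20.0),
    ("Elstera", "Rhodospirillaceae", "Rhodospirillales", "Alphaproteobacteria", "Proteobacteria", 0.52, 150.0),
    ("Hyphomonas", "Hyphomonadaceae", "Rhodobacterales", "Alphaproteobacteria", "Proteobacteria", 0.55, 6.0),
    ("Pseudomonas", "Pseudomonadaceae", "Pseudomonadales", "Gammaproteobacteria", "Proteobacteria", 0.58, 110.0),
    ("Rhodobacter", "Rhodobacteraceae", "Rhodobacterales", "Alphaproteobacteria", "Proteobacteria", 0.61, 25.0),
    ("Mesorhizobium", "Phyllobacteriaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria", 0.64, 180.0),
    ("Bosea", "Bradyrhizobiaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria", 0.67, 12.0),
    ("Brevundimonas", "Caulobacteraceae", "Caulobacterales", "Alphaproteobacteria", "Proteobacteria", 0.70, 70.0),
    ("Silanimonas", "Xanthomonadaceae", "Xanthomonadales", "Gammaproteobacteria", "Proteobacteria", 0.73, 30.0),
    ("Pseudoxanthomonas", "Xanthomonadaceae", "Xanthomonadales", "Gammaproteobacteria", "Proteobacteria", 0.76, 130.0),
]


def example_community(
    n_epibionts: int = 12,
    label_noise: float = 0.0,
    seed: int = 0,
    genome_length_scale: float = 1.0,
) -> CommunitySpec:
    """A dominant-cyanobacterium community spec with distinct epibionts.

    The dominant genome sits at 43% GC and high coverage, holding
    roughly half of the community sequence mass; ``n_epibionts``
    (8-16) genomes are drawn from a fixed palette of distinct
    (GC, coverage) signatures. Genome lengths are hundreds of kbp —
    scaled-down stand-ins for real Mbp genomes that keep whole-pipeline
    runs fast; scale up with ``genome_length_scale``.
    """
    if not 2 <= n_epibionts <= len(_EPIBIONT_PALETTE):
        raise ValueError(f"n_epibionts must lie in [2, {len(_EPIBIONT_PALETTE)}]")
    universe = default_marker_universe()
    single_copy = {m: 1 for m in universe}
    genomes = [
        GenomeSpec(
            genome_id="Microcystis_dom",
            taxon_lineage=("Microcystis aeruginosa", "Microcystis",
                           "Microcystaceae", "Chroococcales",
                           "Oscillatoriophycideae", "Cyanobacteria"),
            gc_target=0.43,
            coverage_mean=250.0,
            coverage_cv=0.12,
            genome_length=int(400_000 * genome_length_scale),
            n_scaffolds=20,
            marker_copy_numbers=single_copy,
        )
    ]
    for i, (genus, fam, order, cls, phylum, gc, cov) in enumerate(
        _EPIBIONT_PALETTE[:n_epibionts], start=1
    ):
        genomes.append(
            GenomeSpec(
                genome_id=f"{genus}_e{i:02d}",
                taxon_lineage=(f"{genus} sp.", genus, fam, order, cls, phylum),
                gc_target=gc,
                coverage_mean=cov,
                coverage_cv=0.12,
                genome_length=int(180_000 * genome_length_scale),
                n_scaffolds=15,
                marker_copy_numbers=single_copy,
            )
        )
    return CommunitySpec(
        genomes=tuple(genomes), label_noise=label_noise, hit_redundancy=5, seed=seed
    )


_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


def synthetic_proteomes(
    spec: CommunitySpec,
    seed: int,
    proteins_per_genome: int = 120,
    protein_length: int = 250,
) -> dict[str, list[tuple[str, str]]]:
    """Random i.i.d. amino-acid proteomes, one per genome.

    A deliberately simple stand-in (no evolutionary model): each genome
    gets independent random proteins, so composition-vector distances
    between genomes are near the unrelated-pair baseline. Sufficient to
    exercise proteome I/O and tree construction end to end.
    """
    rng = np.random.default_rng(seed)
    proteomes: dict[str, list[tuple[str, str]]] = {}
    for g in spec.genomes:
        seqs = []
        for i in range(1, proteins_per_genome + 1):
            aa = rng.choice(_AA, size=protein_length)
            seqs.append((f"{g.genome_id}_p{i:04d}", aa.tobytes().decode("ascii")))
        proteomes[g.genome_id] = seqs
    return proteomes
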
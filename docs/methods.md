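# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the
choices made where the underlying protocol was manual or unspecified.

## Scaffold filtering and assembly statistics

Scaffolds enter the pipeline with a mean read depth attached (computed
upstream, e.g. by `genomeCoverageBed`). The filter keeps scaffolds with
length ≥ 200 bp and coverage ≥ 3×; both boundaries are inclusive,
reading the stated minima as attainable values. GC is computed over
unambiguous bases only — `N` counts toward neither numerator nor
denominator, and all-`N` scaffolds are rejected rather than scored.

N50 uses the descending-cumulative-sum convention: sort lengths
descending and return the length at which the running total first
reaches half the assembly. No interpolation; a single-contig assembly
has N50 equal to its length. The convention is property-tested against
a brute-force definition (largest L such that contigs ≥ L hold half
the total).

## GC × coverage binning

Each scaffold maps to (GC, log₁₀ coverage). Axes are centered and
scaled to unit variance, except that each axis's scale is floored at
1 GC percentage point and 0.05 log₁₀-coverage units: when an assembly
contains essentially one cloud (or identical points), standardization
would otherwise magnify measurement noise into apparent structure.
The stored scale factors make the transform invertible.

The reference protocol drew bin boundaries by eye around the clouds in
this plane. The package's default realization is DBSCAN on the
standardized plane:

| parameter | default | meaning |
|---|---|---|
| `eps` | 0.3 | DBSCAN reachability radius (standardized units) |
| `min_samples` | 5 | weighted neighbor mass to be a core point |
| `min_cluster_size` | 5 | scaffolds needed for a cluster to become a bin |
| `rescue_distance_threshold` | 2.0 | max centroid distance for marker rescue |

Points are weighted by ⌈log₁₀ length⌉ in the density estimate, so long
scaffolds anchor clusters the way they dominate a scatter plot
visually. Clusters below `min_cluster_size` dissolve into the
unassigned pool. Bins are labeled `bin01, bin02, …` by descending
total length, so the dominant genome is `bin01`. For faithful
visual-guided operation a polygon file (bin label, GC, log₁₀ coverage
per vertex row) replaces the clusterer with point-in-polygon tests.

**Marker rescue.** After clustering, an unassigned scaffold carrying at
least one essential single-copy gene is attached to the nearest bin
centroid iff that distance is ≤ `rescue_distance_threshold`
(configurable per sample); otherwise it stays unassigned. This is a
deliberate restraint: pulling in *every* marker-bearing fragment
contaminates bins with whatever the assembler failed to place cleanly.
Non-marker fragments are never rescued; rescue never creates, empties,
or reshuffles bins. Equidistant centroids are resolved toward the
larger bin, then the lexicographically smaller label.

## Marker census

Completeness and contamination derive from a universe of 107 essential
single-copy genes (genes conserved in ~95% of sequenced bacteria):

- completeness = 100 · |{m : copies(m) ≥ 1}| / 107
- contamination = 100 · Σ_m max(0, copies(m) − 1) / 107

Contamination counts *extra copies*, so a badly mixed bin can exceed
100%. A marker split across two scaffolds counts twice (we count hit
rows); this overestimates contamination slightly on fragmented
assemblies. The marker identity list ships as a replaceable
configuration file — the bundled file is a synthetic stand-in universe
of 107 ids, and none of the mathematics depends on which ids they are.
Percentages are reported to two decimals.

## Taxonomic assignment and consistency

Gene hits arrive as BLAST outfmt-6 rows with six lineage columns
(species…phylum) appended. Filters: E-value ≤ 1e−5 (inclusive),
identity > 60% (strict), query coverage > 50% (strict), then the 100
best rows per gene by bitscore (ties: lower E-value, then file order).
outfmt-6 carries no query-length column, so query length is taken as
the maximum `qend` observed for the gene — in practice every gene
retains one near-full-length alignment, which pins it.

Each gene votes once, for its best retained labeled hit (`best_hit`
mode; a `fractional` mode splitting the vote across all retained hits
is available). Consistency = 100 · (votes for the modal taxon) /
(genes with a vote); genes with no retained hits are excluded from the
denominator. The bin is assigned at genus if consistency > 65%
(strict); otherwise votes are recast at family rank from the hits —
not by promoting the failed genus vote, since one family can reunite
several genera — and the same test applies; otherwise the bin is
unclassified, reporting the better of the two modal fractions. A bin
with *zero* voting genes is unclassified with consistency 100: among
zero voters there is no dissent, and such bins (high completeness, no
database matches) are candidates for novel lineages rather than poor
bins. Composite labels ("Rhizobium/Agrobacterium group") are atomic
strings. Gene→scaffold linkage follows the ORF-caller convention
`<scaffold>_<ordinal>`.

## Quality rubric and abundance

The five tiers test (completeness C, contamination X, consistency S,
contig count N), boundaries inclusive on the attainable side:

- ★★★★★ nearly complete: (C≥95 ∧ X≤5 ∧ S≥90 ∧ N≤10) ∨ (C≥90 ∧ X≤5 ∧ S≥80 ∧ N≤3)
- ★★★★ good draft: C≥90 ∧ X≤5 ∧ S≥80
- ★★★ moderate draft: C≥70 ∧ X≤10 ∧ S≥65
- ★★ partial: C≥50 ∧ X≤15 ∧ S≥65
- ★ disqualified: anything else

The source table prints thresholds without comparators; the
directionality above is the only one under which the tiers nest, and
nesting makes the rubric monotone: improving any input never lowers
the tier (property-tested over a boundary grid and random dominance
pairs).

Relative abundance of bin b = 100 · Σ_{s∈b} len(s)·cov(s) / Σ len·cov
over binned scaffolds — an estimate of read-mass share, scale-invariant
in coverage. Unassigned scaffolds are excluded from the denominator by
default (reports then sum to ~100%); a toggle includes them. The
community report lists bins by ascending abundance with a totals row.

## Composition-vector phylogeny

For a proteome, count all k-, (k−1)- and (k−2)-peptides (k = 6 by
default, configurable 3–8; peptides containing characters outside the
20 standard amino acids are skipped). With observed frequency f(α) of
k-peptide α = a₁…a_k, the (k−2)-order Markov background is

    f₀(α) = f(a₁…a_{k−1}) · f(a₂…a_k) / f(a₂…a_{k−1})

and the vector entry is (f − f₀)/f₀ where f₀ > 0, else 0. The
subtraction removes shared low-order compositional signal, leaving the
deviations that carry phylogenetic information. Pairwise dissimilarity
is d = (1 − cos θ)/2 ∈ [0, 1] over the union of supports.

Neighbor joining is implemented in-package: Q-criterion minimization
with the standard limb-length formulas, terminating in a trifurcating
root (the unrooted tree). Negative limb lengths are clamped to zero
with the deficit moved to the sister limb, preserving pairwise path
lengths. Q-ties break toward the smallest index pair, making the
agglomeration order deterministic. On additive matrices the output
path lengths reproduce the input exactly (tested for 4–8 taxa, with an
independent library implementation as a topology cross-check).
Bootstrap support is out of scope; the Newick writer emits plain
branch lengths.

## Synthetic communities

The generator realizes a `CommunitySpec` — a list of genome blueprints
plus hit-table emission parameters — into scaffolds, coverage, marker
hits, gene hits, and complete ground truth. It emulates:

- **Community structure**: one dominant cyanobacterium-like genome
  (43% GC, 250× coverage, ~37–60% of read mass depending on epibiont
  count) plus 8–16 epibionts whose (GC, coverage) signatures are
  placed on a grid — GC values 0.03 apart with alternating low/high
  coverages — so any two genomes separate in at least one axis.
- **Sequence**: i.i.d. nucleotides with an exact (rounded) G+C base
  count per scaffold, so realized GC matches the target to well within
  one percentage point. No codon structure, repeats, or chimeras:
  downstream stages consume only GC, length, coverage, and labels.
- **Coverage**: per-scaffold depth ~ Gamma(mean = coverage_mean,
  CV = coverage_cv), truncated at 0.01 — strictly positive and
  right-skewed like mapped depth. Default CV 0.12, the scale of
  scaffold-level mean-depth variation within one genome.
- **Markers**: every copy in `marker_copy_numbers` lands on exactly one
  length-weighted scaffold of its genome.
- **Gene hits**: ~1 gene/kbp; each gene emits `hit_redundancy` rows
  (default 5, cap 100). The best row is full-length, high-identity,
  and carries the true lineage with probability 1 − `label_noise`;
  with probability `label_noise` it carries a random other genome's
  lineage. Lower-ranked rows have random lineages, partial alignments,
  and weaker scores, so the quality filters have real work to do.

Identical spec + seed ⇒ byte-identical output files; all randomness
flows through one explicit `numpy` generator.

Genome lengths default to hundreds of kbp — scaled-down stand-ins for
real Mbp genomes chosen so a full multi-seed benchmark suite runs in
minutes on one CPU; `genome_length_scale` restores realistic sizes.
What passing tests show is that the *algorithms* recover planted
structure under these idealized conditions (clean separation, no
misassembly, no shared k-mer content between genomes); they do not
show robustness to chimeric scaffolds, strain mixtures, or
database-incompleteness effects in real data. The optional synthetic
proteomes are i.i.d. amino-acid draws — enough to exercise proteome
I/O and tree construction, but carrying no planted phylogeny (all
between-genome distances sit near the unrelated-pair baseline ~0.25).

## Numerical and degenerate-input policy

- Filter and rubric boundaries inclusive as stated above; taxonomy
  identity/coverage filters strict, E-value inclusive.
- Consistency threshold strict (> 65), so a modal share of exactly 65%
  is unclassified.
- Empty bins score completeness 0, contamination 0. Empty assemblies
  cannot be summarized (error). Zero-norm composition vectors and
  sub-k proteomes are rejected.
- Projection requires positive coverage (guaranteed post-filter;
  checked anyway).
- All percentages print to two decimals; bin sizes in Mb to two
  decimals.

## Known limitations

- DBSCAN defaults were chosen for communities whose genomes separate
  by ≥ 0.03 GC or ≥ 0.3 log₁₀-coverage (the generator's "separable"
  certificate); denser communities need per-sample tuning or the
  polygon escape hatch, exactly as the visual protocol needed a
  per-sample eye.
- The best-hit vote is one reading of an under-specified consensus
  procedure; the `fractional` switch covers the other.
- Contamination by hit-row counting double-counts split markers.
- The bundled marker list is a placeholder universe, not the real
  essential-gene set; swap in a curated list for real analyses.
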
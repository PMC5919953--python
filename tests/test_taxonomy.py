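"""Hit filtering, per-gene votes, consistency, and the rank-fallback rule."""

import pandas as pd
import pytest

from microbin.synthetic import GENE_HIT_COLUMNS
from microbin.taxonomy import (
    HitFilterParams,
    Rank,
    assign_bin,
    filter_hits,
    gene_taxon,
    gene_votes,
    scaffold_of_gene,
)


def hit(gene="s1_1", pident=90.0, qstart=1, qend=200, evalue=1e-20,
        bitscore=500.0, genus="Brevundimonas", family="Caulobacteraceae",
        species="Brevundimonas sp."):
    return {
        "qseqid": gene, "sseqid": "ref", "pident": pident, "length": qend - qstart + 1,
        "mismatch": 0, "gapopen": 0, "qstart": qstart, "qend": qend,
        "sstart": 1, "send": qend - qstart + 1, "evalue": evalue,
        "bitscore": bitscore, "species": species, "genus": genus,
        "family": family, "order": "o", "class": "c", "phylum": "p",
    }


def table(rows):
    return pd.DataFrame(rows, columns=list(GENE_HIT_COLUMNS))


class TestFilterHits:
    def test_identity_boundary_is_strict(self):
        rows = table([hit(pident=60.0), hit(pident=60.1)])
        kept = filter_hits(rows)
        assert kept["pident"].tolist() == [60.1]

    def test_evalue_boundary_is_inclusive(self):
        rows = table([hit(evalue=1e-5), hit(evalue=1.1e-5)])
        kept = filter_hits(rows)
        assert kept["evalue"].tolist() == [1e-5]

    def test_query_coverage_boundary_is_strict(self):
        # full-length hit fixes qlen=200; spans of 100 (50%) vs 101 (50.5%)
        rows = table([
            hit(bitscore=600.0),
            hit(qstart=1, qend=100, bitscore=500.0),
            hit(qstart=1, qend=101, bitscore=400.0),
        ])
        kept = filter_hits(rows)
        assert kept["bitscore"].tolist() == [600.0, 400.0]

    def test_per_gene_cap_keeps_best_by_bitscore(self):
        rows = table([hit(bitscore=100.0 + i) for i in range(150)])
        kept = filter_hits(rows)
        assert len(kept) == 100
        assert kept["bitscore"].min() == 150.0

    def test_cap_applies_per_gene_not_globally(self):
        rows = table(
            [hit(gene="s1_1", bitscore=100.0 + i) for i in range(120)]
            + [hit(gene="s1_2", bitscore=100.0 + i) for i in range(120)]
        )
        kept = filter_hits(rows)
        assert kept.groupby("qseqid").size().tolist() == [100, 100]


class TestGeneTaxon:
    def test_single_hit(self):
        rows = table([hit(genus="Brevundimonas")])
        assert gene_taxon(rows, Rank.GENUS) == "Brevundimonas"

    def test_no_rows_gives_none(self):
        assert gene_taxon(table([]), Rank.GENUS) is None

    def test_best_bitscore_wins(self):
        rows = table([hit(genus="Loser", bitscore=400.0),
                      hit(genus="Winner", bitscore=500.0)])
        assert gene_taxon(rows, Rank.GENUS) == "Winner"

    def test_bitscore_tie_broken_by_evalue(self):
        rows = table([hit(genus="Worse", bitscore=500.0, evalue=1e-10),
                      hit(genus="Better", bitscore=500.0, evalue=1e-30)])
        assert gene_taxon(rows, Rank.GENUS) == "Better"

    def test_unlabeled_best_hit_falls_through(self):
        rows = table([hit(genus="", bitscore=600.0),
                      hit(genus="Named", bitscore=500.0)])
        assert gene_taxon(rows, Rank.GENUS) == "Named"


def _bin_hits(votes: dict[str, int], family_of=None):
    """One gene per vote, each with a single dominating hit."""
    family_of = family_of or {}
    rows = []
    i = 0
    for genus, n in votes.items():
        for _ in range(n):
            i += 1
            rows.append(hit(gene=f"s1_{i}", genus=genus,
                            family=family_of.get(genus, f"fam_{genus}")))
    return filter_hits(table(rows))


class TestAssignBin:
    def test_clear_genus_majority(self):
        hits = _bin_hits({"Brevundimonas": 80, "Other": 20})
        t = assign_bin("b", hits)
        assert t.rank == Rank.GENUS
        assert t.taxon == "Brevundimonas"
        assert t.consistency == pytest.approx(80.0)
        assert t.n_assigned_genes == 100

    def test_threshold_is_strictly_greater_than_65(self):
        hits = _bin_hits({"A": 65, "B": 35})  # exactly 65% at genus and family
        t = assign_bin("b", hits)
        assert t.rank == Rank.UNCLASSIFIED
        assert t.taxon is None

    def test_zero_voting_genes_reports_consistency_100(self):
        t = assign_bin("novel", filter_hits(table([])))
        assert t.rank == Rank.UNCLASSIFIED
        assert t.consistency == 100.0
        assert t.n_assigned_genes == 0

    def test_family_fallback_reunites_split_genera(self):
        # three genera of one family, none above 65% alone
        hits = _bin_hits(
            {"GenusA": 40, "GenusB": 35, "GenusC": 25},
            family_of={"GenusA": "SharedFam", "GenusB": "SharedFam",
                       "GenusC": "SharedFam"},
        )
        t = assign_bin("b", hits)
        assert t.rank == Rank.FAMILY
        assert t.taxon == "SharedFam"
        assert t.consistency == pytest.approx(100.0)

    def test_composite_labels_are_atomic(self):
        hits = _bin_hits({"Rhizobium/Agrobacterium group": 90, "X": 10})
        t = assign_bin("b", hits)
        assert t.taxon == "Rhizobium/Agrobacterium group"

    def test_consistency_invariant_under_gene_order(self):
        hits = _bin_hits({"A": 50, "B": 30})
        shuffled = hits.sample(frac=1, random_state=0)
        assert assign_bin("b", hits).consistency == \
               assign_bin("b", shuffled).consistency

    def test_adding_modal_votes_never_decreases_consistency(self):
        base = {"A": 60, "B": 40}
        prev = assign_bin("b", _bin_hits(base)).consistency
        for extra in (10, 30, 60):
            cons = assign_bin("b", _bin_hits({"A": 60 + extra, "B": 40})).consistency
            assert cons >= prev
            prev = cons


def test_fractional_voting_mode_runs():
    rows = table([hit(gene="s1_1", genus="A", bitscore=500.0),
                  hit(gene="s1_1", genus="B", bitscore=450.0),
                  hit(gene="s1_2", genus="A")])
    votes = gene_votes(filter_hits(rows), Rank.GENUS, method="fractional")
    assert votes["s1_1"]["A"] == pytest.approx(0.5)
    t = assign_bin("b", filter_hits(rows), method="fractional")
    assert t.taxon == "A"


def test_scaffold_of_gene_convention():
    assert scaffold_of_gene("NODE_12_length_993_1") == "NODE_12_length_993"
    with pytest.raises(ValueError):
        scaffold_of_gene("no-ordinal")


def test_planted_genus_recovered_from_generator_output(small_community):
    """End-to-end vote on ground-truth bins of the noise-free community."""
    c = small_community
    retained = filter_hits(c.gene_hits)
    retained = retained.assign(
        scaffold_id=[scaffold_of_gene(g) for g in retained["qseqid"]]
    )
    for g in c.spec.genomes:
        members = {sid for sid, gid in c.truth.scaffold_to_genome.items()
                   if gid == g.genome_id}
        t = assign_bin(g.genome_id,
                       retained[retained["scaffold_id"].isin(members)])
        assert t.rank == Rank.GENUS
        assert t.taxon == g.taxon_lineage[1]
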
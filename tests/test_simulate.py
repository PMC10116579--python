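"""Synthetic-data generators: reproducibility and ground-truth consistency."""

import numpy as np
import pytest

from orcensus._seq import STOP_CODONS, revcomp, translate
from orcensus.expression import ks_two_sample, normalized_position, summarize_expression
from orcensus.simulate import (
    FamilySimParams,
    GenomeSimParams,
    OsnSimParams,
    ReceptorSimSpec,
    build_synthetic_genome,
    pseudogenize,
    random_orf,
    simulate_gene_family,
    simulate_osn_positions,
)

TREE3 = "((A:50,B:50):50,C:100);"


class TestGeneFamilySim:
    def test_no_rates_gives_congruent_single_copy(self):
        t = simulate_gene_family(FamilySimParams(TREE3, 0, 0, seed=1))
        assert t.gene_tree == "((A_g1,B_g1),C_g1);"
        assert t.total_duplications == t.total_losses == 0
        assert t.extant_counts == {"A": 1, "B": 1, "C": 1}
        assert set(t.ancestral_counts.values()) == {1}

    def test_huge_loss_rate_extinct(self):
        t = simulate_gene_family(FamilySimParams(TREE3, 0.0, 1000.0, seed=1))
        assert t.extinct and t.gene_tree is None

    def test_reproducible_by_seed(self):
        a = simulate_gene_family(FamilySimParams(TREE3, 0.01, 0.005, seed=9))
        b = simulate_gene_family(FamilySimParams(TREE3, 0.01, 0.005, seed=9))
        c = simulate_gene_family(FamilySimParams(TREE3, 0.01, 0.005, seed=10))
        assert a == b
        assert a != c

    def test_pure_birth_expectation_single_branch(self):
        """E[N(t)] = e^(lambda t) for a pure-birth copy on one branch."""
        ns = [
            simulate_gene_family(FamilySimParams("(A:100);", 0.01, 0.0, seed=i)).extant_counts["A"]
            for i in range(400)
        ]
        m, se = np.mean(ns), np.std(ns) / np.sqrt(len(ns))
        assert abs(m - np.e) <= 3.5 * se

    def test_event_counts_nonnegative_and_leafcounts_consistent(self):
        t = simulate_gene_family(FamilySimParams(TREE3, 0.01, 0.01, seed=3))
        assert all(d >= 0 and l >= 0 for d, l in t.branch_events.values())
        if not t.extinct:
            for sp, n in t.extant_counts.items():
                assert t.gene_tree.count(f"{sp}_g") == n


class TestPseudogenize:
    def test_no_events_identity(self, orf300):
        cds, _ = orf300
        mutated, truth = pseudogenize(cds, [], seed=0)
        assert mutated == cds and truth == []

    def test_planted_stop_codon(self, orf300):
        cds, _ = orf300
        mutated, truth = pseudogenize(cds, [("premature_stop", 150)], seed=4)
        assert mutated[450:453] in STOP_CODONS
        assert [(e.kind, e.cds_position) for e in truth] == [("premature_stop", 150)]
        assert len(mutated) == len(cds)

    def test_frameshift_changes_length_by_1_or_2(self, orf300):
        cds, _ = orf300
        mutated, truth = pseudogenize(cds, [("frameshift", 300)], seed=4)
        assert abs(len(mutated) - len(cds)) in (1, 2)
        assert truth[0].kind == "frameshift" and truth[0].cds_position == 300

    def test_position_outside_cds_errors(self, orf300):
        cds, _ = orf300
        with pytest.raises(ValueError, match="outside"):
            pseudogenize(cds, [("premature_stop", 900)], seed=0)

    def test_invalid_orf_rejected(self):
        with pytest.raises(ValueError):
            pseudogenize("ACGTACGT", 1, seed=0)


class TestSyntheticGenome:
    def test_zero_divergence_complete_gene_translates_to_template(self):
        params = GenomeSimParams(
            divergence=0.0,
            status_plan=[("OR", "complete")],
            intron_every=0,
            seed=2,
        )
        genome, truth = build_synthetic_genome(params)
        g = truth.genes[0]
        seq = genome.contigs[g.contig_id][g.start : g.end]
        if g.strand == "-":
            seq = revcomp(seq)
        assert translate(seq) == g.protein + "*"
        assert g.protein == truth.queries["OR_tpl1"]

    def test_edge_gene_near_contig_end(self):
        params = GenomeSimParams(status_plan=[("OR", "edge")], seed=3)
        genome, truth = build_synthetic_genome(params)
        g = truth.genes[0]
        L = len(genome.contigs[g.contig_id])
        assert min(g.start, L - g.end) < 5000

    def test_truncated_gene_far_from_ends(self):
        params = GenomeSimParams(status_plan=[("OR", "truncated")], seed=3)
        genome, truth = build_synthetic_genome(params)
        g = truth.genes[0]
        L = len(genome.contigs[g.contig_id])
        assert min(g.start, L - g.end) >= 5000

    def test_census_and_gff_reflect_plan(self):
        genome, truth = build_synthetic_genome(GenomeSimParams(seed=4))
        census = truth.census().set_index("family")
        assert census.loc["OR"].tolist() == [3, 1, 1, 1]
        assert census.loc["TAAR"].tolist() == [2, 1, 0, 0]
        assert census.loc["V1R_ORA"].tolist() == [1, 0, 0, 0]
        gff = truth.gff3()
        assert gff.startswith("##gff-version 3")
        assert gff.count("\tgene\t") == 10

    def test_reproducible_by_seed(self):
        g1, t1 = build_synthetic_genome(GenomeSimParams(seed=6))
        g2, t2 = build_synthetic_genome(GenomeSimParams(seed=6))
        assert g1.contigs == g2.contigs
        assert [vars(a) for a in t1.genes] == [vars(b) for b in t2.genes]

    def test_contig_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            build_synthetic_genome(GenomeSimParams(contig_length=5_000, seed=1))


class TestOsnSim:
    def test_uniform_beta_mean_half(self):
        params = OsnSimParams(
            receptors={"u": ReceptorSimSpec(400, 1.0, 1.0, 0.5)}, seed=1
        )
        cells, _ = simulate_osn_positions(params)
        pos = [normalized_position(c) for c in cells]
        assert abs(np.mean(pos) - 0.5) < 4 / np.sqrt(len(pos))

    def test_all_primary_when_p_is_one(self):
        params = OsnSimParams(receptors={"p": ReceptorSimSpec(100, 2, 2, 1.0)}, seed=2)
        cells, lamellae = simulate_osn_positions(params)
        s = summarize_expression(cells, lamellae)
        assert (s.pct_primary, s.pct_secondary) == (100.0, 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_beta_shape_contrast_detected(self, seed):
        """Beta(2,5) vs Beta(5,2) receptors, n=200 each: KS p < 0.001."""
        params = OsnSimParams(
            receptors={
                "apical": ReceptorSimSpec(200, 2, 5, 0.5),
                "basal": ReceptorSimSpec(200, 5, 2, 0.5),
            },
            seed=seed,
        )
        cells, _ = simulate_osn_positions(params)
        x = [normalized_position(c) for c in cells if c.receptor_id == "apical"]
        y = [normalized_position(c) for c in cells if c.receptor_id == "basal"]
        assert ks_two_sample(x, y).p_value < 1e-3

    def test_reproducible_by_seed(self):
        a_cells, a_lam = simulate_osn_positions(OsnSimParams(seed=7))
        b_cells, b_lam = simulate_osn_positions(OsnSimParams(seed=7))
        assert a_cells == b_cells and a_lam == b_lam
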
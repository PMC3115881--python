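"""Synthetic genome generator and tree-evolved alignments."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mitocomp.composition import composition_profile, whole_genome_profile
from mitocomp.distances import jc_model, p_distance
from mitocomp.genetic_code import STOP_CODONS, translate
from mitocomp.genome_io import (
    ANCESTRAL_INSECT_ORDER,
    compare_gene_orders,
    extract_gene_sequence,
    gene_order_signature,
)
from mitocomp.synthetic import (
    ControlRegionSpec,
    GenomeSpec,
    TreeSpec,
    evolve_alignment,
    fixture_cohort,
    generate_genome,
)


class TestGenerateGenome:
    def test_same_seed_byte_identical(self):
        g1 = generate_genome(GenomeSpec(seed=5))
        g2 = generate_genome(GenomeSpec(seed=5))
        assert g1.sequence == g2.sequence
        assert g1.features == g2.features

    def test_different_seeds_differ(self):
        assert (generate_genome(GenomeSpec(seed=5)).sequence
                != generate_genome(GenomeSpec(seed=6)).sequence)

    def test_has_all_37_genes_in_requested_order(self, genome7):
        sig = gene_order_signature(genome7)
        assert sig == ANCESTRAL_INSECT_ORDER

    def test_pcgs_are_clean_orfs(self, genome7):
        for f in genome7.gene_features():
            if f.category != "PCG":
                continue
            cds = extract_gene_sequence(genome7, f.name)
            body = cds[: len(cds) - len(cds) % 3]
            aa = translate(body)
            assert "*" not in aa[:-1], f.name
            assert cds[:3] == "ATG"
            assert cds[-3:] in STOP_CODONS

    def test_composition_targets_met_within_tolerance(self):
        for seed in (1, 2, 3):
            g = generate_genome(GenomeSpec(seed=seed, at_pct=78.0,
                                           at_skew=0.02, gc_skew=-0.20))
            p = whole_genome_profile(g)
            assert abs(p.at_pct - 78.0) < 1.5
            assert abs(p.at_skew - 0.02) < 0.03
            assert abs(p.gc_skew - (-0.20)) < 0.03

    def test_pure_at_control_region(self):
        cr = ControlRegionSpec(at_pct=100.0, gc_skew=0.0,
                               homopolymers=(), repeats=())
        g = generate_genome(GenomeSpec(seed=4, control_region=cr))
        seq = extract_gene_sequence(g, "control_region")
        assert set(seq) <= {"A", "T"}

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(seed=1, at_pct=120.0)
        with pytest.raises(ValueError):
            GenomeSpec(seed=1, start_codon="CCC")

    def test_trnc_translocation_travels_through_pipeline(self, neuroptera_genome):
        sig = gene_order_signature(neuroptera_genome)
        rep = compare_gene_orders(sig, ANCESTRAL_INSECT_ORDER)
        assert rep.repositioned == ("trnC",)

    def test_control_region_homopolymers_planted(self, genome7):
        from mitocomp.motifs import homopolymer_runs, run_length_ranges
        cr = extract_gene_sequence(genome7, "control_region")
        ranges = run_length_ranges(homopolymer_runs(cr, min_len=3))
        assert ranges["A"][1] >= 11
        assert ranges["T"][1] >= 8


class TestEvolveAlignment:
    def test_zero_length_star_tree_identical_rows(self):
        aln = evolve_alignment(
            TreeSpec("(A:0.0,B:0.0,C:0.0);", jc_model(), 500, seed=1))
        assert len(set(aln.rows)) == 1

    def test_determinism(self):
        s = TreeSpec("(A:0.1,B:0.1);", jc_model(), 800, seed=2)
        assert evolve_alignment(s).rows == evolve_alignment(s).rows

    def test_two_taxa_jc_expected_p_distance(self):
        """p ≈ (3/4)(1−e^(−4t/3)) within 3 binomial SE at t=0.3."""
        t = 0.3
        n = 10_000
        aln = evolve_alignment(
            TreeSpec(f"(A:{t / 2},B:{t / 2});", jc_model(), n, seed=3))
        expected = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(expected * (1 - expected) / n)
        observed = p_distance(aln).matrix[0, 1]
        assert abs(observed - expected) < 3 * se

    def test_equilibrium_frequencies_at_50kb(self):
        from mitocomp.distances import gtr_model
        freqs = np.array([0.4, 0.1, 0.15, 0.35])
        model = gtr_model(freqs, np.ones(6))
        aln = evolve_alignment(TreeSpec("(A:0.5,B:0.5);", model, 50_000, seed=4))
        counts = np.array([aln.rows[0].count(c) for c in "ACGT"])
        stat, pval = chisquare(counts, f_exp=freqs * counts.sum())
        assert pval > 1e-4

    def test_gamma_rates_increase_pattern_dispersion(self):
        flat = evolve_alignment(TreeSpec("(A:0.5,B:0.5);", jc_model(), 20_000, 5))
        gam = evolve_alignment(
            TreeSpec("(A:0.5,B:0.5);", jc_model(alpha=0.2), 20_000, 5))
        # strong rate variation concentrates differences on fewer sites
        assert (p_distance(gam).matrix[0, 1] < p_distance(flat).matrix[0, 1])

    def test_bad_newick_rejected(self):
        with pytest.raises(Exception):
            evolve_alignment(TreeSpec("not a tree", jc_model(), 100, seed=6))


class TestFixtureCohort:
    def test_requested_cluster_regimes_recovered(self):
        from mitocomp.composition import assign_clusters
        regimes = [
            {"at_pct": 67.0, "at_skew": 0.12, "gc_skew": -0.27},
            {"at_pct": 72.5, "at_skew": 0.07, "gc_skew": -0.31},
            {"at_pct": 77.5, "at_skew": 0.02, "gc_skew": -0.22},
            {"at_pct": 82.0, "at_skew": -0.03, "gc_skew": -0.17},
            {"at_pct": 87.0, "at_skew": 0.01, "gc_skew": -0.12},
        ]
        expected_at = ["A1", "A2", "A3", "A4", "A5"]
        cohort = fixture_cohort(5, regimes, seed=31)
        for g, exp in zip(cohort, expected_at):
            lab = assign_clusters(whole_genome_profile(g))
            assert lab.at_cluster == exp

    def test_singleton_cohort(self):
        assert len(fixture_cohort(1, seed=1)) == 1

    def test_same_seed_identical_cohorts(self):
        c1 = fixture_cohort(3, seed=9)
        c2 = fixture_cohort(3, seed=9)
        assert [g.sequence for g in c1] == [g.sequence for g in c2]
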
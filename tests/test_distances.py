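"""p-distances and ML model-corrected distances."""

import numpy as np
import pytest

from mitocomp.distances import (
    Alignment,
    discrete_gamma_rates,
    empirical_freqs,
    estimate_gtr,
    gtr_model,
    jc_correct,
    jc_model,
    load_aa_model,
    ml_distance,
    ml_pair_distance,
    p_distance,
    poisson_aa_model,
)
from mitocomp.synthetic import TreeSpec, evolve_alignment


def jc_count_matrix(p: float, n: int = 120_000) -> np.ndarray:
    """Pair count matrix with exactly fraction p of uniform differences."""
    ndiff = p * n
    cm = np.full((4, 4), ndiff / 12.0)
    np.fill_diagonal(cm, (n - ndiff) / 4.0)
    return cm


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert p_distance(aln).matrix[0, 1] == 0.0

    def test_one_difference_in_four(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        assert p_distance(aln).matrix[0, 1] == 0.25

    def test_pairwise_vs_complete_deletion(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "AC-T", "ACGA"])
        pw = p_distance(aln, "pairwise")
        assert pw.eff_sites[0, 1] == 3      # gap excluded for that pair only
        assert pw.eff_sites[0, 2] == 4
        comp = p_distance(aln, "complete")
        assert comp.eff_sites[0, 2] == 3    # gapped column dropped for all

    def test_no_comparable_sites_raises(self):
        aln = Alignment(["a", "b"], ["A---", "-CGT"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln)


class TestMlDistance:
    @pytest.mark.parametrize("p", [0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    def test_jc_closed_form_agreement(self, p):
        """Single-rate equal-everything model must match the JC formula."""
        d, capped = ml_pair_distance(jc_count_matrix(p), jc_model())
        assert not capped
        assert d == pytest.approx(jc_correct(p), abs=1e-6)

    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b"], ["ACGT" * 50] * 2)
        assert ml_distance(aln, jc_model()).matrix[0, 1] == 0.0

    def test_poisson_aa_closed_form(self):
        """One difference in 100 sites under the uniform 20-state model."""
        n, ndiff = 10_000, 100
        cm = np.full((20, 20), ndiff / 380.0)
        np.fill_diagonal(cm, (n - ndiff) / 20.0)
        d, _ = ml_pair_distance(cm, poisson_aa_model())
        expected = -(19 / 20) * np.log(1 - (20 / 19) * 0.01)
        assert d == pytest.approx(expected, abs=1e-6)

    def test_corrected_geq_p_distance(self):
        aln = evolve_alignment(TreeSpec("(A:0.4,B:0.4,C:0.1);", jc_model(), 3000, 9))
        pm = p_distance(aln)
        dm = ml_distance(aln, jc_model())
        for i, j, d in dm.pairs():
            assert d >= pm.matrix[i, j]
            if pm.matrix[i, j] > 0:
                assert d > pm.matrix[i, j]

    def test_row_order_invariance(self):
        aln = evolve_alignment(TreeSpec("(A:0.2,B:0.2,C:0.05);", jc_model(), 2000, 4))
        shuffled = Alignment(list(reversed(aln.ids)), list(reversed(aln.rows)))
        d1 = ml_distance(aln, jc_model())
        d2 = ml_distance(shuffled, jc_model())
        for a in aln.ids:
            for b in aln.ids:
                i1, j1 = d1.ids.index(a), d1.ids.index(b)
                i2, j2 = d2.ids.index(a), d2.ids.index(b)
                assert d1.matrix[i1, j1] == pytest.approx(d2.matrix[i2, j2], abs=1e-6)

    def test_saturated_pair_capped_and_flagged(self):
        d, capped = ml_pair_distance(jc_count_matrix(0.74999999), jc_model())
        assert capped and d >= 9.8

    def test_recovery_of_true_path_length(self):
        """Median relative error below 5% on 10 kb pairs."""
        errors = []
        model = jc_model()
        for k, t in enumerate([0.05, 0.2, 0.5, 1.0]):
            for rep in range(5):
                aln = evolve_alignment(
                    TreeSpec(f"(A:{t / 2},B:{t / 2});", model, 10_000, 1000 + 17 * k + rep))
                d = ml_distance(aln, model).matrix[0, 1]
                errors.append(abs(d - t) / t)
        assert np.median(errors) < 0.05


class TestModels:
    def test_discrete_gamma_rates_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0)
            assert (np.diff(r) > 0).all()

    def test_rate_matrix_scaled_to_unit_mean_rate(self):
        m = gtr_model(np.array([0.4, 0.1, 0.2, 0.3]), [1, 2, 3, 4, 5, 6])
        q = m.exchangeabilities * m.freqs[None, :]
        np.fill_diagonal(q, 0)
        assert (m.freqs * q.sum(axis=1)).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("name", ["mtrev24", "jtt"])
    def test_empirical_aa_models_load(self, name):
        m = load_aa_model(name)
        assert m.freqs.sum() == pytest.approx(1.0)
        assert m.n_states == 20
        assert (m.exchangeabilities >= 0).all()
        assert np.allclose(m.exchangeabilities, m.exchangeabilities.T)

    def test_transition_matrix_rows_sum_to_one(self):
        m = load_aa_model("jtt", alpha=0.5)
        p = m.transition_matrix(0.3)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_mixture_with_pinv_identity_at_zero_time(self):
        m = gtr_model(np.full(4, 0.25), np.ones(6), alpha=0.5, pinv=0.2)
        assert np.allclose(m.mixture_transition(0.0), np.eye(4))

    def test_estimate_gtr_recovers_transition_bias(self):
        """AG/CT-rich simulated data should yield elevated AG and CT rates."""
        truth = gtr_model(np.full(4, 0.25), [1, 8, 1, 1, 8, 1])
        aln = evolve_alignment(TreeSpec("(A:0.2,B:0.2,C:0.2,D:0.05);", truth, 4000, 21))
        est = estimate_gtr(aln)
        s = est.exchangeabilities
        ag, ct = s[0, 2], s[1, 3]
        transversions = [s[0, 1], s[0, 3], s[1, 2], s[2, 3]]
        assert ag > 2 * max(transversions)
        assert ct > 2 * max(transversions)

    def test_empirical_freqs(self):
        aln = Alignment(["a", "b"], ["AAAA", "AACG"])
        f = empirical_freqs(aln)
        assert f[0] == pytest.approx(6 / 8)
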
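"""m-slope regression, quartet likelihood mapping, %FRQ, marker profiles."""

import numpy as np
import pytest

from mitocomp.distances import Alignment, DistanceMatrix, jc_model, p_distance
from mitocomp.saturation import frq, m_slope, marker_profiles, quartet_likelihoods
from mitocomp.synthetic import TreeSpec, evolve_alignment


def dm(ids, values, flagged=None):
    m = np.array(values, dtype=float)
    d = DistanceMatrix(ids, m, "test", np.full_like(m, 100.0))
    if flagged is not None:
        d.flagged = np.array(flagged, dtype=bool)
    return d


class TestMSlope:
    def test_identity_data_slope_one(self):
        ids = ["a", "b", "c"]
        x = dm(ids, [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        assert m_slope(x, x) == pytest.approx(1.0)

    def test_half_slope(self):
        ids = ["a", "b", "c"]
        y = dm(ids, [[0, 0.05, 0.1], [0.05, 0, 0.15], [0.1, 0.15, 0]])
        x = dm(ids, [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        assert m_slope(y, x) == pytest.approx(0.5)

    def test_flagged_pairs_excluded(self, caplog):
        ids = ["a", "b", "c"]
        y = dm(ids, [[0, 0.1, 0.7], [0.1, 0, 0.1], [0.7, 0.1, 0]])
        flags = [[0, 0, 1], [0, 0, 0], [1, 0, 0]]
        x = dm(ids, [[0, 0.1, 10.0], [0.1, 0, 0.1], [10.0, 0.1, 0]], flags)
        with caplog.at_level("WARNING"):
            assert m_slope(y, x) == pytest.approx(1.0)
        assert "excluded" in caplog.text

    def test_too_few_pairs_raise(self):
        ids = ["a", "b"]
        x = dm(ids, [[0, 0.1], [0.1, 0]], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            m_slope(x, x)

    def test_slope_decreases_with_tree_depth(self):
        """Deeper trees are more saturated: m strictly decreasing."""
        from mitocomp.distances import ml_distance
        means = []
        for depth in (0.1, 0.5, 1.5):
            vals = []
            for rep in range(5):
                nwk = f"((A:{depth},B:{depth}):{depth / 2},(C:{depth},D:{depth}):{depth / 2});"
                aln = evolve_alignment(
                    TreeSpec(nwk, jc_model(), 2000, seed=100 * rep + int(depth * 10)))
                vals.append(m_slope(p_distance(aln), ml_distance(aln, jc_model())))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        assert all(m <= 1.0 + 1e-9 for m in means)


class TestQuartets:
    def test_identical_sequences_map_to_center(self):
        aln = Alignment(list("abcd"), ["ACGTACGT" * 12] * 4)
        q = quartet_likelihoods(aln, list("abcd"), jc_model(), seed=1)
        assert q.region == "center"
        assert q.weights == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-6)

    def test_weights_sum_to_one(self):
        aln = evolve_alignment(
            TreeSpec("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.0);", jc_model(), 500, 3))
        q = quartet_likelihoods(aln, ["A", "B", "C", "D"], jc_model(), seed=2)
        assert sum(q.weights) == pytest.approx(1.0, abs=1e-12)

    def test_identical_pairs_pull_to_pairing_corner(self):
        """AA|BB data must resolve the topology joining the identical taxa."""
        rng = np.random.default_rng(5)
        s1 = "".join(rng.choice(list("ACGT"), 100))
        s2 = "".join(rng.choice(list("ACGT"), 100))
        aln = Alignment(["w", "x", "y", "z"], [s1, s1, s2, s2])
        q = quartet_likelihoods(aln, ["w", "x", "y", "z"], jc_model(), seed=6)
        assert q.region == "corner1"  # topology 1 pairs (w,x) with (y,z)
        q2 = quartet_likelihoods(aln, ["w", "y", "x", "z"], jc_model(), seed=7)
        assert q2.region == "corner2"  # now the pairing is the second topology

    def test_long_internal_branch_fully_resolved(self):
        aln = evolve_alignment(TreeSpec(
            "((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.0);", jc_model(), 5000, 8))
        q = quartet_likelihoods(aln, ["A", "B", "C", "D"], jc_model(), seed=9)
        assert q.region == "corner1"
        assert max(q.weights) > 0.99


class TestFrq:
    def test_four_taxa_gives_all_or_nothing(self):
        aln = evolve_alignment(TreeSpec(
            "((A:0.05,B:0.05):0.4,(C:0.05,D:0.05):0.0);", jc_model(), 2000, 10))
        assert frq(aln, jc_model(), seed=11) in (0.0, 100.0)

    def test_fewer_than_four_taxa_rejected(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        with pytest.raises(ValueError):
            frq(aln, jc_model(), seed=0)

    def test_resolved_tree_beats_star_tree(self):
        """Tree-like data approaches 100%; star-tree data falls well below."""
        resolved = evolve_alignment(TreeSpec(
            "(((A:0.05,B:0.05):0.3,(C:0.05,D:0.05):0.3):0.01,(E:0.05,F:0.05):0.3);",
            jc_model(), 2000, 12))
        star = evolve_alignment(TreeSpec(
            "(A:0.3,B:0.3,C:0.3,D:0.3,E:0.3,F:0.3);", jc_model(), 2000, 13))
        f_resolved = frq(resolved, jc_model(), seed=14)
        f_star = frq(star, jc_model(), seed=15)
        assert f_resolved >= 90.0
        assert f_star < f_resolved - 40.0


def test_marker_profiles_two_rate_contrast(genome7):
    """A 4x faster gene shows lower m-slope and higher avg-pd."""
    slow = evolve_alignment(TreeSpec(
        "((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.02);", jc_model(), 1500, 16))
    fast = evolve_alignment(TreeSpec(
        "((A:0.2,B:0.2):0.4,(C:0.2,D:0.2):0.08);", jc_model(), 1500, 17))
    df = marker_profiles([genome7], {"slow_gene": slow, "fast_gene": fast},
                         seed=18).set_index("marker")
    assert df.loc["fast_gene", "avg_pd"] > df.loc["slow_gene", "avg_pd"]
    assert df.loc["fast_gene", "m_slope"] < df.loc["slow_gene", "m_slope"]
    for col in ("frq", "m_slope", "avg_pd"):
        assert np.isfinite(df[col]).all()
    assert (df.frq.between(0, 100)).all()
    assert (df.avg_pd.between(0, 1)).all()


def test_marker_profiles_pooled_enc(genome7):
    aln = evolve_alignment(TreeSpec(
        "((A:0.05,B:0.05):0.2,(C:0.05,D:0.05):0.02);", jc_model(), 900, 19))
    df = marker_profiles([genome7], {"pooled-a+b": aln}, seed=20)
    enc_val = df.avg_enc.iloc[0]
    assert 20 <= enc_val <= 62
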
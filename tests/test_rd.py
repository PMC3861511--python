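"""The directed relative-distance statistic and its pairwise bundle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdselect.rd import (
    RDOptions,
    directed_rds_from_dist,
    euclidean_distance,
    pairwise_rd,
    rd_directed,
    squared_diff_tensor,
)

from conftest import brute_pair_rds, brute_rd, make_matrix


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1.0, 2.0], [1.0, 2.0], 0.0),
            ([0.0, 0.0], [3.0, 4.0], 5.0),
            ([1.0, 2.0, 3.0], [2.0, 0.0, 5.0], 3.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert euclidean_distance(x, y) == pytest.approx(expected, abs=1e-15)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            euclidean_distance([1.0], [1.0, 2.0])


class TestRdDirected:
    def test_degenerate_spreads_give_unit_margin(self):
        A = np.zeros((3, 1))
        B = np.ones((3, 1))
        c = rd_directed(0, A, B)
        assert c.d_between == (1.0, 1.0, 1.0)
        assert c.sd_a1b == 0.0 and c.md_aa == 0.0 and c.sd_aa == 0.0
        assert c.rd == pytest.approx(1.0)

    def test_identical_groups_give_zero(self):
        A = np.full((3, 2), 1.5)
        c = rd_directed(1, A, A.copy())
        assert c.rd == 0.0
        assert c.md_a1b == 0.0 and c.md_aa == 0.0

    def test_hand_derived_triplet_example(self):
        # A = {0,1,2}, B = {10,11,12}, focal a1=0:
        # d_between = 10,11,12 -> md 11, sd 1; d_within = 1,2 -> md 1.5,
        # sd = sqrt(0.5); rd = 11 - 1 - 1.5 - sqrt(0.5)
        A = np.array([[0.0], [1.0], [2.0]])
        B = np.array([[10.0], [11.0], [12.0]])
        c = rd_directed(0, A, B)
        assert c.d_between == (10.0, 11.0, 12.0)
        assert c.md_a1b == pytest.approx(11.0)
        assert c.sd_a1b == pytest.approx(1.0)
        assert c.md_aa == pytest.approx(1.5)
        assert c.sd_aa == pytest.approx(np.sqrt(0.5))
        assert c.rd == pytest.approx(7.792893218813452, abs=1e-12)

    def test_population_sd_option(self):
        A = np.array([[0.0], [1.0], [2.0]])
        B = np.array([[10.0], [11.0], [12.0]])
        c = rd_directed(0, A, B, RDOptions(sd="population"))
        expected = brute_rd(0, A.tolist(), B.tolist(), sd="population")
        assert c.rd == pytest.approx(expected, abs=1e-12)

    def test_ratio_form(self):
        A = np.array([[0.0], [1.0], [2.0]])
        B = np.array([[10.0], [11.0], [12.0]])
        c = rd_directed(0, A, B, RDOptions(form="ratio"))
        assert c.rd == pytest.approx((11.0 - 1.5) / (1.0 + np.sqrt(0.5)), abs=1e-12)

    def test_two_replicate_groups_generalize(self):
        A = np.array([[0.0], [0.5]])
        B = np.array([[5.0], [6.0]])
        c = rd_directed(0, A, B)
        assert c.d_within == (0.5,)
        assert c.sd_aa == 0.0  # single within distance: SD defined as 0
        assert c.rd == pytest.approx((5.5 - np.std([5.0, 6.0], ddof=1)) - 0.5)

    def test_mismatched_gene_sets_raise(self):
        with pytest.raises(ValueError):
            rd_directed(0, np.zeros((3, 2)), np.zeros((3, 3)))


class TestBruteForceAgreement:
    @pytest.mark.parametrize("j", [1, 2, 5, 61])
    def test_matches_scalar_oracle(self, j, rng):
        for _ in range(25):
            A = rng.normal(size=(3, j))
            B = rng.normal(size=(3, j)) + rng.normal()
            for focal in range(3):
                got = rd_directed(focal, A, B).rd
                want = brute_rd(focal, A.tolist(), B.tolist())
                assert got == pytest.approx(want, abs=1e-12)

    def test_vectorized_kernel_matches_rd_directed(self, rng):
        vals = rng.normal(size=(4, 6))
        m = make_matrix(vals, n_reps=3)
        d2 = squared_diff_tensor(vals)
        for opts in (RDOptions(), RDOptions(sd="population"), RDOptions(form="ratio")):
            sub = [0, 2]
            dist = np.sqrt(d2[sub].sum(axis=0))
            fast = directed_rds_from_dist(dist, np.arange(3), np.arange(3, 6), opts)
            slow = pairwise_rd(m, ("g001", "g003"), "grp1", "grp2", opts).rd_values
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestPairwiseRd:
    def test_six_values_and_mean(self, two_group_matrix):
        res = pairwise_rd(two_group_matrix, ("g001", "g002"), "ctrlA", "ctrlB")
        assert len(res.rd_values) == 6
        assert res.mean_rd == pytest.approx(np.mean(res.rd_values))
        assert res.discriminates

    def test_outlier_replicate_breaks_discrimination(self):
        # third A replicate placed inside B's cloud
        vals = np.array([[0.0, 0.1, 5.0, 5.0, 5.1, 4.9]])
        m = make_matrix(vals, group_names=["A", "B"])
        res = pairwise_rd(m, ("g001",), "A", "B")
        assert min(res.rd_values) < 0
        assert not res.discriminates

    def test_zero_rd_fails_strict_discrimination(self):
        vals = np.zeros((1, 6))
        m = make_matrix(vals, group_names=["A", "B"])
        res = pairwise_rd(m, ("g001",), "A", "B")
        assert res.rd_values == (0.0,) * 6
        assert not res.discriminates

    def test_unknown_group_or_gene_raises(self, two_group_matrix):
        with pytest.raises(KeyError):
            pairwise_rd(two_group_matrix, ("g001",), "ctrlA", "nope")
        with pytest.raises(KeyError):
            pairwise_rd(two_group_matrix, ("nope",), "ctrlA", "ctrlB")

    def test_empty_gene_set_raises(self, two_group_matrix):
        with pytest.raises(ValueError):
            pairwise_rd(two_group_matrix, (), "ctrlA", "ctrlB")


profiles = st.integers(1, 4).flatmap(
    lambda j: st.lists(
        st.lists(st.floats(-50, 50, allow_nan=False, width=32), min_size=j, max_size=j),
        min_size=6,
        max_size=6,
    )
)


class TestInvariants:
    @given(profiles, st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_translation_invariance(self, prof, shift):
        A = np.array(prof[:3], dtype=float)
        B = np.array(prof[3:], dtype=float)
        base = rd_directed(0, A, B)
        moved = rd_directed(0, A + shift, B + shift)
        assert moved.rd == pytest.approx(base.rd, abs=1e-8)
        assert moved.md_a1b == pytest.approx(base.md_a1b, abs=1e-8)
        assert moved.sd_aa == pytest.approx(base.sd_aa, abs=1e-8)

    @given(profiles, st.floats(0.01, 100, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, prof, c):
        A = np.array(prof[:3], dtype=float)
        B = np.array(prof[3:], dtype=float)
        base = rd_directed(1, A, B)
        scaled = rd_directed(1, c * A, c * B)
        assert scaled.rd == pytest.approx(c * base.rd, rel=1e-7, abs=1e-7)
        assert scaled.md_aa == pytest.approx(c * base.md_aa, rel=1e-7, abs=1e-7)

    @given(profiles)
    @settings(max_examples=60, deadline=None)
    def test_pair_symmetry(self, prof):
        m = make_matrix(np.array(prof, dtype=float).T, group_names=["A", "B"])
        ab = pairwise_rd(m, m.gene_ids, "A", "B")
        ba = pairwise_rd(m, m.gene_ids, "B", "A")
        assert sorted(ab.rd_values) == pytest.approx(sorted(ba.rd_values), abs=1e-12)
        assert ab.mean_rd == pytest.approx(ba.mean_rd, abs=1e-12)
        assert ab.discriminates == ba.discriminates


class TestNullBehaviour:
    def test_false_discrimination_rate_falls_with_spread(self):
        """Under identical group distributions the all-six-positive event
        becomes rarer as within-group spread grows relative to a fixed
        between-group shift."""
        rng = np.random.default_rng(99)
        shift = 1.0
        rates = []
        for sigma in (0.5, 1.5, 4.5):
            hits = 0
            for _ in range(1000):
                A = rng.normal(0.0, sigma, size=(3, 1))
                B = rng.normal(shift, sigma, size=(3, 1))
                rds = brute_pair_rds(A.tolist(), B.tolist())
                hits += all(v > 0 for v in rds)
            rates.append(hits / 1000)
        assert rates[0] > rates[1] > rates[2]
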
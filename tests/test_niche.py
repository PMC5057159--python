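"""Niche-overlap, breadth, richness and null-model unit tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichepart.niche import (NullModelResult, chao1, combined_similarity,
                             group_overlap, levins, pianka, ra3_null,
                             rarefy_chao1)
from nichepart.raster import InputError

from conftest import make_composition


class TestPianka:
    @pytest.mark.parametrize("p,q,expected", [
        ([0.2, 0.3, 0.5], [0.2, 0.3, 0.5], 1.0),                # identity
        ([1, 0, 0, 0], [0, 0, 0.4, 0.6], 0.0),                  # disjoint
        ([0.5, 0.5, 0.0], [0.0, 0.5, 0.5], 0.5),                # hand value
    ])
    def test_known_values(self, p, q, expected):
        assert pianka(np.array(p), np.array(q)) == pytest.approx(
            expected, abs=1e-9)

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
           st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_bounded_scale_invariant(self, raw, scale):
        p = np.array(raw)
        q = np.roll(p, 1)
        o1 = pianka(p, q)
        assert o1 == pytest.approx(pianka(q, p), abs=1e-12)
        assert -1e-12 <= o1 <= 1 + 1e-12
        # scaling a vector before normalization changes nothing
        assert pianka(p * scale, q) == pytest.approx(o1, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(InputError):
            pianka(np.zeros(3), np.array([1.0, 0, 0]))


class TestLevins:
    @pytest.mark.parametrize("p,expected", [
        (np.full(7, 1 / 7), 7.0),                 # uniform over k -> k
        (np.array([1.0, 0, 0]), 1.0),             # single resource
        (np.array([0.5, 0.25, 0.25]), 1 / 0.375),  # hand value 2.667
    ])
    def test_known_values(self, p, expected):
        assert levins(p) == pytest.approx(expected, abs=1e-9)


class TestChao1:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 3, 2, 2, 4], 5.0),                          # F1=0 -> S_obs
        ([1, 1, 1, 1, 2, 2, 3, 3, 5, 9], 10 + 16 / 4),   # F1=4, F2=2
        ([1, 1, 1, 4, 5], 5 + 3 * 2 / 2),                # F2=0 bias-corrected
    ])
    def test_known_values(self, counts, expected):
        assert chao1(np.array(counts)) == pytest.approx(expected, abs=1e-9)

    def test_never_below_observed_richness(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 6, size=20)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    def test_matches_scikit_bio(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        for _ in range(20):
            counts = rng.integers(0, 8, size=30)
            if (counts == 2).sum() == 0:
                continue  # skbio uses the same F2>0 formula; compare there
            assert chao1(counts) == pytest.approx(
                skbio_alpha.chao1(counts, bias_corrected=False), abs=1e-9)


class TestGroupOverlap:
    def test_identical_rows_give_unit_overlap(self):
        cm = make_composition(np.tile([0.2, 0.3, 0.5], (4, 1)),
                              groups=["A", "A", "B", "B"])
        res = group_overlap(cm)
        for key in ("within_A", "within_B", "between_pairs_mean",
                    "between_pooled"):
            assert res[key] == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_groups(self):
        cm = make_composition([[1, 0, 0, 0], [1, 0, 0, 0],
                               [0, 0, 1, 0], [0, 0, 1, 0]],
                              groups=["A", "A", "B", "B"])
        res = group_overlap(cm)
        assert res["within_A"] == pytest.approx(1.0)
        assert res["within_B"] == pytest.approx(1.0)
        assert res["between_pairs_mean"] == pytest.approx(0.0)

    def test_means_equal_bruteforce_enumeration(self, rng):
        values = rng.dirichlet(np.ones(5), size=4)
        groups = ["A", "A", "B", "B"]
        cm = make_composition(values, groups=groups)
        res = group_overlap(cm)
        within_a = pianka(values[0], values[1])
        within_b = pianka(values[2], values[3])
        between = np.mean([pianka(values[i], values[j])
                           for i in (0, 1) for j in (2, 3)])
        assert res["within_A"] == pytest.approx(within_a, abs=1e-12)
        assert res["within_B"] == pytest.approx(within_b, abs=1e-12)
        assert res["between_pairs_mean"] == pytest.approx(between, abs=1e-12)


class TestRA3:
    def test_two_category_null_matches_enumeration(self, rng):
        # with 2 categories each row permutation is keep-or-swap: the exact
        # null is the distribution of the statistic over all 2^n arrangements
        values = rng.dirichlet(np.ones(2), size=6)
        groups = ["A"] * 3 + ["B"] * 3
        cm = make_composition(values, groups=groups)
        exact = []
        for flips in itertools.product([0, 1], repeat=6):
            v = np.array([row[::-1] if f else row
                          for row, f in zip(values, flips)])
            exact.append(group_overlap(
                make_composition(v, groups=groups))["between_pooled"])
        exact = np.sort(exact)
        res = ra3_null(cm, statistic="between", n_iter=4000, seed=11)
        # the simulated null support is a subset of the enumerated support
        assert set(np.round(res.null, 12)) <= set(np.round(exact, 12))
        assert res.null.mean() == pytest.approx(exact.mean(), abs=0.02)

    def test_levins_breadth_preserved_by_randomization(self, rng):
        # RA3 permutes within rows: niche breadth (sum p^2) is invariant
        values = rng.dirichlet(np.ones(6), size=5)
        before = [levins(row) for row in values]
        perm = rng.permuted(values, axis=1)
        after = [levins(row) for row in perm]
        assert np.allclose(sorted(before), sorted(after))

    def test_single_category_degenerate(self):
        cm = make_composition([[1.0], [1.0], [1.0], [1.0]],
                              groups=["A", "A", "B", "B"])
        res = ra3_null(cm, n_iter=10, seed=0)
        assert res.degenerate
        assert res.p_high == 1.0 and res.p_low == 1.0

    def test_identical_rows_high_overlap_detected(self):
        cm = make_composition(np.tile([0.1, 0.2, 0.3, 0.25, 0.15], (8, 1)),
                              groups=["A"] * 4 + ["B"] * 4)
        res = ra3_null(cm, statistic="between", n_iter=999, seed=3)
        assert res.observed == pytest.approx(1.0)
        assert res.p_high <= 0.05
        assert isinstance(res, NullModelResult)
        assert res.p_high + res.p_low >= 1.0

    def test_tail_convention(self, rng):
        values = rng.dirichlet(np.ones(4), size=6)
        cm = make_composition(values, groups=["A"] * 3 + ["B"] * 3)
        res = ra3_null(cm, statistic="within:A", n_iter=99, seed=5)
        assert len(res.null) == 99
        assert 0 < res.p_high <= 1 and 0 < res.p_low <= 1
        assert res.p_high + res.p_low >= 1.0


class TestRarefaction:
    def test_endpoint_equals_pooled_chao1(self, rng):
        counts = rng.integers(0, 5, size=(6, 12))
        counts[:, 0] += 1
        est = rarefy_chao1(counts, n_boot=50, seed=1)
        assert est.curve_mean[-1] == pytest.approx(est.chao1, abs=1e-9)
        mean, sd = est.at(6)
        assert mean == pytest.approx(est.chao1)
        assert sd == pytest.approx(0.0)

    def test_duplicated_units_give_flat_curve(self):
        row = np.array([3, 1, 0, 2, 5])
        counts = np.tile(row, (5, 1))
        est = rarefy_chao1(counts, n_boot=40, seed=2)
        # m=1 may differ (singletons scale); beyond that pooling duplicates
        # only multiplies counts and the estimate is constant
        assert np.allclose(est.curve_mean[1:], est.curve_mean[1])

    def test_chao1_at_least_observed(self, rng):
        counts = rng.integers(0, 3, size=(8, 15))
        counts[0, 0] += 1
        est = rarefy_chao1(counts, n_boot=30, seed=3)
        assert est.chao1 >= est.s_obs

    def test_rejects_tiny_inputs(self):
        with pytest.raises(InputError):
            rarefy_chao1(np.array([[1, 2, 3]]), n_boot=10, seed=0)


class TestCombinedSimilarity:
    def test_printed_three_axis_product(self):
        res = combined_similarity({"habitat": 0.50, "timing": 0.83,
                                   "diet": 0.29})
        assert res["product_rounded"] == pytest.approx(0.12)

    def test_identity_and_annihilator(self):
        base = {"a": 0.37, "b": 0.81}
        with_one = combined_similarity({**base, "c": 1.0})
        assert with_one["product"] == pytest.approx(0.37 * 0.81)
        with_zero = combined_similarity({**base, "c": 0.0})
        assert with_zero["product"] == 0.0

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            combined_similarity({"a": 1.2})
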
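import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import kruskal_h, mann_whitney_exact_p
from itsfold.stats import describe, holm_adjust, kruskal_wallis, mann_whitney_u


class TestMannWhitney:
    def test_worked_example_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_method == "exact"

    def test_perfect_symmetry_with_ties(self):
        res = mann_whitney_u([1, 2], [1, 2], seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert res.p_method == "permutation"

    def test_two_sided_symmetric_in_groups(self):
        x, y = [1.0, 5.0, 2.5], [3.0, 9.0, 0.5, 7.0]
        assert mann_whitney_u(x, y).p_value == pytest.approx(mann_whitney_u(y, x).p_value)

    def test_exact_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1, n + m + 1)).astype(float)  # tie-free
            x, y = pooled[:n].tolist(), pooled[n:].tolist()
            for alt in ("two_sided", "less", "greater"):
                res = mann_whitney_u(x, y, alternative=alt)
                assert res.p_method == "exact"
                assert res.p_value == pytest.approx(mann_whitney_exact_p(x, y, alt))

    def test_permutation_close_to_enumeration_with_ties(self):
        x, y = [1, 1, 2, 3], [2, 2, 3, 4]
        res = mann_whitney_u(x, y, seed=1, n_permutations=100_000)
        assert res.p_method == "permutation"
        assert res.p_value == pytest.approx(mann_whitney_exact_p(x, y), abs=0.02)

    def test_large_samples_use_normal_approx(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 20).tolist()
        y = rng.normal(1, 1, 20).tolist()
        res = mann_whitney_u(x, y)
        assert res.p_method == "normal_approx"
        assert res.p_value < 0.05

    def test_constant_pooled_data_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            res = mann_whitney_u([2, 2], [2, 2, 2])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(st.floats(min_value=0.1, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_monotone_shift_never_increases_greater_p(self, c):
        x = [1.0, 3.0, 4.5, 7.0]
        y = [2.0, 5.0, 6.0, 8.0]
        p0 = mann_whitney_u(x, y, alternative="greater").p_value
        p1 = mann_whitney_u([v + c for v in x], y, alternative="greater").p_value
        assert p1 <= p0 + 1e-12


class TestKruskalWallis:
    def test_constant_groups(self):
        with pytest.warns(UserWarning):
            res = kruskal_wallis([[5, 5], [5, 5], [5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_h_matches_hand_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_h(groups))

    def test_two_group_agreement_with_mann_whitney(self):
        rng = np.random.default_rng(13)
        agree = 0
        for k in range(30):
            vals = rng.permutation(1000)[:16].astype(float)
            x, y = vals[:8].tolist(), vals[8:].tolist()
            if k % 2:
                y = [v + 2000 for v in y]  # inject a clear shift, still tie-free
            p_mw = mann_whitney_u(x, y).p_value
            p_kw = kruskal_wallis([x, y]).p_value
            agree += (p_mw < 0.05) == (p_kw < 0.05)
        assert agree >= 28  # chi-square vs exact differ only at the margin

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.uniform(0, 10, 6).tolist() for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDescribe:
    def test_basic_summary(self):
        s = describe([1, 2, 3])
        assert (s.mean, s.sd, s.min, s.max) == (2.0, 1.0, 1.0, 3.0)

    def test_mode_most_frequent(self):
        assert describe([7, 7, 3]).mode == 7

    def test_mode_tie_breaks_to_smallest(self):
        assert describe([2, 3]).mode == 2

    def test_single_value_sd_zero(self):
        assert describe([4.2]).sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestHolm:
    def test_monotone_and_bounded(self):
        p = [0.01, 0.04, 0.03, 0.5]
        adj = holm_adjust(p)
        assert all(0 <= v <= 1 for v in adj)
        assert adj[0] == pytest.approx(0.04)
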
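"""Reliability statistics: classical tests, ICCs, permutation, power."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import trochleamap as tm
from trochleamap.errors import NumericalError, ValidationError
from trochleamap.stats import MANN_WHITNEY_ARE

from oracles import anova_icc_bruteforce


# ---------------------------------------------------------------------------
# Mann-Whitney / Fisher / Holm
# ---------------------------------------------------------------------------

def _mwu_enumeration_p(a, b):
    """Exact two-sided MWU p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(sel):
        grp_a = [pooled[i] for i in sel]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in sel]
        return sum((x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b)

    obs = u_stat(range(na))
    n, k = len(pooled), na
    mean_u = na * (n - na) / 2
    count = total = 0
    for sel in itertools.combinations(range(n), k):
        u = u_stat(set(sel))
        total += 1
        if abs(u - mean_u) >= abs(obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = tm.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_identical_groups_give_p_one(self):
        _, p = tm.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.95

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(10):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 11 - na))
            a = rng.normal(size=na).round(2)
            b = rng.normal(size=nb).round(2)
            _, p = tm.mann_whitney(a, b)
            assert p == pytest.approx(_mwu_enumeration_p(a, b), abs=1e-9)

    def test_detects_published_effect_size_in_simulation(self):
        # group means/SDs 31.8±10.3 vs 16.3±9.4 at n=30 per group:
        # the difference is detected at p < .001 in at least 95% of seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            a = r.normal(31.8, 10.3, 30)
            b = r.normal(16.3, 9.4, 30)
            _, p = tm.mann_whitney(a, b)
            hits += p < 0.001
        assert hits >= 0.95 * n_seeds

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            tm.mann_whitney([], [1.0])


class TestFisherExact:
    def test_published_sex_ratio_table(self):
        assert tm.fisher_exact([[24, 6], [22, 8]]) == pytest.approx(0.76, abs=0.005)

    def test_perfect_separation(self):
        assert tm.fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_symmetric_table_is_one(self):
        assert tm.fisher_exact([[3, 3], [3, 3]]) == pytest.approx(1.0)

    def test_agrees_with_hypergeometric_enumeration(self, rng):
        for _ in range(10):
            t = rng.integers(0, 4, size=(2, 2))
            if t.sum() == 0 or t.sum() > 10:
                continue
            a, b = t[0]
            c, d = t[1]
            n, k1, k2 = t.sum(), a + b, a + c
            probs = {x: sps.hypergeom.pmf(x, n, k1, k2)
                     for x in range(max(0, k1 + k2 - n), min(k1, k2) + 1)}
            p_obs = probs[a]
            expect = sum(v for v in probs.values() if v <= p_obs + 1e-12)
            assert tm.fisher_exact(t) == pytest.approx(expect, abs=1e-9)

    def test_shape_and_sign_validation(self):
        with pytest.raises(ValidationError):
            tm.fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValidationError):
            tm.fisher_exact([[1, -2], [3, 4]])


class TestHolm:
    def test_step_down_hand_computation(self):
        assert np.allclose(tm.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert tm.holm_adjust([0.123])[0] == pytest.approx(0.123)

    def test_ties_cap_and_monotone(self):
        assert np.allclose(tm.holm_adjust([0.5, 0.5, 0.5]), [1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_dominates_raw_p_and_is_monotone(self, ps):
        adj = tm.holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            tm.holm_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_identical_columns_are_perfect_agreement(self):
        col = np.array([1.0, 5.0, 3.0, 8.0, 2.0])
        y = np.column_stack([col, col, col])
        for form in ("A1", "C1"):
            res = tm.icc(y, form)
            assert res.estimate == pytest.approx(1.0)
            assert res.classification == "excellent"

    def test_constant_bias_breaks_agreement_not_consistency(self, rng):
        col = rng.normal(size=10)
        y = np.column_stack([col, col + 5.0])
        assert tm.icc(y, "C1").estimate == pytest.approx(1.0)
        assert tm.icc(y, "A1").estimate < 0.5

    def test_fixed_matrix_matches_bruteforce_oracle(self):
        y = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6],
                      [7, 1, 2], [10, 5, 6], [6, 2, 4]], float)
        assert tm.icc(y, "A1").estimate == pytest.approx(
            anova_icc_bruteforce(y, "A1"), abs=1e-12)
        assert tm.icc(y, "C1").estimate == pytest.approx(
            anova_icc_bruteforce(y, "C1"), abs=1e-12)

    def test_random_matrices_match_bruteforce(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 21))
            k = int(rng.integers(2, 6))
            y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            for form in ("A1", "C1"):
                assert tm.icc(y, form).estimate == pytest.approx(
                    anova_icc_bruteforce(y, form), abs=1e-10)

    def test_matches_pingouin_estimates_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        y = rng.normal(size=(15, 3)) + 2 * rng.normal(size=(15, 1))
        df = pd.DataFrame({
            "s": np.repeat(np.arange(15), 3),
            "r": np.tile(np.arange(3), 15),
            "y": y.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref = ref.set_index("Type")
        for form, key in (("A1", "ICC(A,1)"), ("C1", "ICC(C,1)")):
            res = tm.icc(y, form)
            assert res.estimate == pytest.approx(ref.loc[key, "ICC"], abs=1e-9)
            lo, hi = ref.loc[key, "CI95"]
            assert res.ci_lo == pytest.approx(lo, abs=0.011)
            assert res.ci_hi == pytest.approx(hi, abs=0.011)

    def test_ci_brackets_estimate(self, rng):
        y = rng.normal(size=(8, 3))
        res = tm.icc(y, "A1")
        assert res.ci_lo <= res.estimate <= res.ci_hi

    def test_validation(self, rng):
        with pytest.raises(ValidationError):
            tm.icc(rng.normal(size=(2, 3)), "A1")
        y = rng.normal(size=(5, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValidationError):
            tm.icc(y, "A1")


@pytest.mark.parametrize("value,expected", [
    (0.87, "good"), (0.45, "poor"), (0.91, "excellent"),
    (0.5, "moderate"), (0.75, "good"), (0.9, "excellent"),
    (0.49999, "poor"), (-0.3, "poor"), (1.0, "excellent"),
])
def test_classify_icc_thresholds(value, expected):
    assert tm.classify_icc(value) == expected


def test_classify_icc_rejects_above_one():
    with pytest.raises(ValidationError):
        tm.classify_icc(1.2)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

class TestPermutationICC:
    def test_identical_tables_give_p_one(self, rng):
        y = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1))
        res = tm.permutation_icc_test(y, y.copy(), n_permutations=500, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation_hits_tail(self):
        r = np.random.default_rng(7)
        subj = 10.0 * r.normal(size=(60, 1))
        with_aid = subj + 0.1 * r.normal(size=(60, 3))
        without_aid = 10.0 * r.normal(size=(60, 3))
        res = tm.permutation_icc_test(with_aid, without_aid,
                                      n_permutations=10_000, seed=3)
        assert res.p_value < 0.01

    def test_seed_determinism(self, rng):
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        r1 = tm.permutation_icc_test(a, b, n_permutations=2000, seed=5)
        r2 = tm.permutation_icc_test(a, b, n_permutations=2000, seed=5)
        assert r1.p_value == r2.p_value

    def test_addone_correction_bounds_p(self, rng):
        a = rng.normal(size=(10, 3)) + 3 * rng.normal(size=(10, 1))
        b = rng.normal(size=(10, 3))
        res = tm.permutation_icc_test(a, b, n_permutations=200, seed=0)
        assert 1 / 201 <= res.p_value <= 1.0

    def test_null_p_values_approximately_uniform(self):
        # with/without drawn from the same distribution: KS vs uniform < 0.1
        ps = []
        for s in range(200):
            r = np.random.default_rng(10_000 + s)
            a = r.normal(size=(20, 3)) + 2.0 * r.normal(size=(20, 1))
            b = r.normal(size=(20, 3)) + 2.0 * r.normal(size=(20, 1))
            ps.append(tm.permutation_icc_test(a, b, n_permutations=1000,
                                              seed=s).p_value)
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 0.1

    def test_difference_statistic_variant(self, rng):
        a = rng.normal(size=(25, 3)) + 3 * rng.normal(size=(25, 1))
        b = a + rng.normal(size=(25, 3)) * 4
        res = tm.permutation_icc_test(a, b, n_permutations=2000, seed=2,
                                      statistic="difference")
        assert res.statistic == "difference"
        assert 0 < res.p_value <= 1

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            tm.permutation_icc_test(rng.normal(size=(10, 3)),
                                    rng.normal(size=(9, 3)))


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

class TestSampleSize:
    def test_published_power_analysis_inputs(self):
        assert tm.mw_sample_size(31.8, 10.3, 16.3, 9.4,
                                 alpha=0.05, power=0.8) == 9

    def test_plain_t_route_is_8(self):
        assert tm.mw_sample_size(31.8, 10.3, 16.3, 9.4,
                                 method="t-test") == 8

    def test_halving_the_difference_needs_more_subjects(self):
        base = tm.mw_sample_size(31.8, 10.3, 16.3, 9.4)
        smaller = tm.mw_sample_size(31.8, 10.3, 24.05, 9.4)
        assert smaller > base

    def test_huge_effect_hits_floor(self):
        assert tm.mw_sample_size(100.0, 1.0, 0.0, 1.0) == 3

    def test_are_constant_and_inflation(self):
        assert MANN_WHITNEY_ARE == 0.955
        n_t = tm.mw_sample_size(31.8, 10.3, 16.3, 9.4, method="t-test")
        n_mw = tm.mw_sample_size(31.8, 10.3, 16.3, 9.4)
        assert n_mw == int(np.ceil(n_t / MANN_WHITNEY_ARE))

    def test_equal_means_diverge(self):
        with pytest.raises(NumericalError):
            tm.mw_sample_size(10.0, 1.0, 10.0, 2.0)
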
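"""Two-group comparison machinery: gating, tests, effect sizes, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from npcmorph.group_stats import (
    cohens_d,
    cohens_d_from_data,
    effect_size_r,
    fdr_bh,
    mann_whitney_u,
    pooled_t_test,
    select_test,
    t_from_summary,
    welch_t_test,
)


class TestSelectTest:
    def test_gaussian_equal_variance_takes_pooled_t(self):
        # normal quantile grids: ideally Gaussian-looking, equal spread
        grid = (np.arange(30) + 0.5) / 30
        x = stats.norm.ppf(grid)
        y = stats.norm.ppf(grid) + 0.3
        assert select_test(x, y).test_kind == "pooled_t"

    def test_skewed_sample_routes_to_rank_test(self, rng):
        hits = sum(
            select_test(rng.exponential(1.0, 26), rng.normal(1, 1, 24)).test_kind
            == "mann_whitney"
            for _ in range(50)
        )
        assert hits >= 45  # >= 90% of seeds

    def test_heteroscedastic_gaussians_route_to_welch(self, rng):
        hits = sum(
            select_test(rng.normal(0, 1, 25), rng.normal(0, 4, 25)).test_kind
            == "welch_t"
            for _ in range(50)
        )
        assert hits >= 45

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            select_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTTests:
    def test_identical_samples_give_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = pooled_t_test(x, x)
        assert t == 0.0 and p == 1.0 and df == 6

    def test_matches_direct_formula_on_random_samples(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 2, rng.integers(3, 12))
            t, df, p = pooled_t_test(x, y)
            n1, n2 = len(x), len(y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
            t_ref = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert t == pytest.approx(t_ref, rel=1e-12)
            assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), n1 + n2 - 2), rel=1e-12)

    def test_summary_form_matches_raw_data_test(self, rng):
        """t_from_summary equals the raw test on data with those summaries."""
        x = rng.normal(3, 2, 14)
        y = rng.normal(1, 1, 11)
        for kind, raw in (("pooled", pooled_t_test), ("welch", welch_t_test)):
            t_s, df_s, p_s = t_from_summary(
                x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y),
                kind=kind)
            t_r, df_r, p_r = raw(x, y)
            assert t_s == pytest.approx(t_r, rel=1e-10)
            assert df_s == pytest.approx(df_r, rel=1e-10)
            assert p_s == pytest.approx(p_r, rel=1e-10)

    def test_equal_means_give_zero_t(self):
        t, _, p = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 1, 5, 2, 1, 5, kind="bayes")


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d(3.0, 1.0, 10, 3.0, 2.0, 15) == 0.0

    def test_sign_flips_under_argument_swap(self, rng):
        d1 = cohens_d(2.0, 1.0, 10, 1.0, 1.5, 12)
        d2 = cohens_d(1.0, 1.5, 12, 2.0, 1.0, 10)
        assert d1 == pytest.approx(-d2)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_common_affine_rescaling(self, scale, shift):
        x = np.array([1.0, 2.0, 4.0, 5.5, 3.0])
        y = np.array([2.0, 3.5, 6.0, 4.0])
        d0 = cohens_d_from_data(x, y)
        d1 = cohens_d_from_data(scale * x + shift, scale * y + shift)
        assert d1 == pytest.approx(d0, rel=1e-8)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)


def _u_pair_count(x, y):
    """O(n^2) definition-based U for the first sample (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


class TestMannWhitney:
    def test_u_equals_pair_count_oracle_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, rng.integers(4, 15)).astype(float)
            y = rng.integers(0, 6, rng.integers(4, 15)).astype(float)
            u, z, p = mann_whitney_u(x, y)
            assert u == pytest.approx(_u_pair_count(x, y))

    def test_complete_separation_exact_p(self):
        """n=3 vs 3, x all below y: 2 of the 20 assignments are as extreme."""
        u, z, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_z_zero(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        u, z, p = mann_whitney_u(x, x)
        assert z == 0.0 and p == 1.0

    def test_exact_agrees_with_tie_corrected_normal_at_n8(self, rng):
        """At n1=n2=8 without ties the exact and asymptotic two-sided p
        differ by at most 0.03."""
        sd = math.sqrt(8 * 8 * 17 / 12)
        for _ in range(100):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            u, z, p_exact = mann_whitney_u(x, y)
            zc = max(abs(u - 32.0) - 0.5, 0.0) / sd  # continuity-corrected
            p_norm = 2 * stats.norm.sf(zc)
            assert abs(p_exact - min(p_norm, 1.0)) <= 0.03

    def test_constant_pooled_data(self):
        u, z, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert z == 0.0 and p == 1.0


class TestEffectSizeR:
    @pytest.mark.parametrize(
        "U, n1, n2, expected",
        [(10.50, 26, 24, -0.83), (139.00, 26, 24, -0.48), (312.0, 26, 24, 0.0)],
    )
    def test_untied_normal_approximation(self, U, n1, n2, expected):
        assert effect_size_r(U, n1, n2) == pytest.approx(expected, abs=0.005)

    def test_midpoint_u_is_null(self):
        assert effect_size_r(13 * 11 / 2, 13, 11) == 0.0

    def test_out_of_range_u_rejected(self):
        with pytest.raises(ValueError):
            effect_size_r(700, 26, 24)


def _fdr_oracle(p):
    """Definition-based BH: adj_i = min_{j: p_j >= p_i} min(1, m*p_j/rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    ranks = stats.rankdata(p, method="max")
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        out[i] = min(candidates)
    return out


class TestFdrBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.2]) == pytest.approx([0.2])

    def test_matches_definition_oracle_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 25))
            mine = fdr_bh(p)
            np.testing.assert_allclose(mine, _fdr_oracle(p), atol=1e-12)
            np.testing.assert_allclose(
                mine, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_adjusted_dominates_raw(self, p):
        adj = fdr_bh(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def test_null_p_values_are_uniform(rng):
    """Raw p of the pooled t-test is Uniform(0,1) under the null
    (KS distance < 0.05 at 2000 replicates)."""
    ps = np.empty(2000)
    for i in range(2000):
        ps[i] = pooled_t_test(rng.normal(0, 1, 15), rng.normal(0, 1, 15))[2]
    d = stats.kstest(ps, "uniform").statistic
    assert d < 0.05
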
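"""Permutation tests and Fisher non-parametric combination."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from npcmorph.npc import (
    fisher_combine,
    npc_joint,
    permutation_test,
    run_region_battery,
)


class TestPermutationTest:
    def test_constant_data_gives_p_one(self):
        res = permutation_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], B=100, seed=0)
        assert res.p_value == 1.0

    def test_exhaustive_complete_separation(self):
        """n=4 vs 4, full separation: exactly the observed labeling and its
        mirror reach the maximal |U - center| among all 70 relabelings."""
        res = permutation_test([1, 2, 3, 4], [10, 11, 12, 13], B=10, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 70
        assert res.p_value == pytest.approx(2 / 70)

    def test_monte_carlo_matches_enumeration_within_binomial_error(self, rng):
        """At n=5 vs 5 the B=5000 Monte Carlo p lands within 3 binomial SEs
        of the exhaustive p."""
        x = rng.normal(0.8, 1, 5)
        y = rng.normal(0, 1, 5)
        exact = permutation_test(x, y, B=1, seed=0).p_value  # exhaustive branch
        mc = permutation_test(x, y, B=5000, seed=1, exhaustive_threshold=0).p_value
        se = math.sqrt(exact * (1 - exact) / 5000)
        assert abs(mc - exact) <= 3 * se + 1 / 5001

    def test_mean_difference_statistic_supported(self, rng):
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        res = permutation_test(x, y, statistic="mean_diff", B=500, seed=2,
                               exhaustive_threshold=0)
        assert res.observed == pytest.approx(x.mean() - y.mean())
        assert 1 / 501 <= res.p_value <= 1.0

    def test_seeded_determinism(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        a = permutation_test(x, y, B=300, seed=9, exhaustive_threshold=0)
        b = permutation_test(x, y, B=300, seed=9, exhaustive_threshold=0)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.permuted, b.permuted)

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1, 2], [3, 4], B=0)


class TestFisherCombine:
    def test_boundary_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == 0.0

    def test_direct_formula(self):
        assert fisher_combine([0.05, 0.05]) == pytest.approx(-4 * math.log(0.05), rel=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(11.98, abs=0.01)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    def test_chi_square_under_independent_uniforms(self, rng):
        """T = -2 sum(ln p) over k=2 independent uniforms is chi^2 with 4 df."""
        draws = np.array([fisher_combine(rng.uniform(size=2)) for _ in range(5000)])
        assert stats.kstest(draws, "chi2", args=(4,)).pvalue > 0.01


class TestNPCJoint:
    def test_duplicated_metric_collapses_to_single_metric_p(self, rng):
        """If both metrics are the same data the joint p equals the
        single-metric empirical p (within the add-one granularity)."""
        x = rng.normal(0.7, 1, 20)
        y = rng.normal(0, 1, 20)
        res = npc_joint({"a": x, "b": x}, {"a": y, "b": y}, B=1000, seed=3)
        assert res.metric_p["a"] == res.metric_p["b"]
        assert abs(res.joint_p - res.metric_p["a"]) <= 1 / 1001 + 1e-12

    def test_synchronized_shuffles_across_metrics(self, rng):
        """A metric that mirrors another metric's values must receive the
        identical shuffles, hence identical per-metric p."""
        x = rng.normal(0.5, 1, 15)
        y = rng.normal(0, 1, 15)
        res = npc_joint({"m": x, "mirror": x.copy()},
                        {"m": y, "mirror": y.copy()}, B=500, seed=11)
        assert res.metric_p["m"] == res.metric_p["mirror"]

    def test_null_joint_p_is_calibrated(self, rng):
        """Both metrics pure noise: joint p averages 0.5 over seeded runs."""
        ps = []
        for i in range(200):
            x = {"t": rng.normal(0, 1, 26), "a": rng.normal(0, 1, 26)}
            y = {"t": rng.normal(0, 1, 24), "a": rng.normal(0, 1, 24)}
            ps.append(npc_joint(x, y, B=200, seed=i).joint_p)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_single_metric_effect_survives_combination(self, rng):
        """d=2 in thickness, nothing in area, n=26/24: the joint test
        rejects at alpha=0.05 in at least 80% of seeds."""
        hits = 0
        for i in range(100):
            x = {"t": rng.normal(2, 1, 26), "a": rng.normal(0, 1, 26)}
            y = {"t": rng.normal(0, 1, 24), "a": rng.normal(0, 1, 24)}
            if npc_joint(x, y, B=2000, seed=i).joint_p < 0.05:
                hits += 1
        assert hits >= 80

    def test_roster_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            npc_joint({"t": rng.normal(0, 1, 10), "a": rng.normal(0, 1, 9)},
                      {"t": rng.normal(0, 1, 8), "a": rng.normal(0, 1, 8)}, B=10)


def _noise_tables(rng, n, regions, metrics):
    import pandas as pd

    idx = [f"s{i}" for i in range(n)]
    return {m: pd.DataFrame(rng.normal(0, 1, (n, len(regions))),
                            index=idx, columns=regions) for m in metrics}


class TestRegionBattery:
    def test_focal_effect_region_has_minimum_adjusted_p(self, rng):
        """One region carries a d=1.5 thickness effect among five; it wins
        the adjusted-p ranking in >= 90% of seeds."""
        import pandas as pd

        regions = [f"r{i}" for i in range(5)]
        labels = ["patient"] * 26 + ["control"] * 24
        wins = 0
        for _ in range(50):
            tables = _noise_tables(rng, 50, regions, ["thickness", "area"])
            tables["thickness"].loc[tables["thickness"].index[:26], "r2"] += 1.5
            res = run_region_battery(tables, labels, regions,
                                     metrics=["thickness", "area"], B=500,
                                     seed=int(rng.integers(2**31)))
            th = res.per_metric[res.per_metric["metric"] == "thickness"]
            wins += th.loc[th["p_adjusted"].idxmin(), "region"] == "r2"
        assert wins >= 45

    def test_null_battery_fdr_calibration(self, rng):
        """Zero-effect battery: the fraction of adjusted p < 0.05 over
        seeds stays at or below the nominal level."""
        regions = [f"r{i}" for i in range(25)]
        labels = ["patient"] * 13 + ["control"] * 12
        flagged = total = 0
        for _ in range(30):
            tables = _noise_tables(rng, 25, regions, ["thickness", "area", "volume"])
            res = run_region_battery(tables, labels, regions, B=400,
                                     seed=int(rng.integers(2**31)))
            flagged += int((res.per_metric["p_adjusted"] < 0.05).sum())
            total += len(res.per_metric)
        assert flagged / total <= 0.05

    def test_unknown_region_rejected(self, rng):
        tables = _noise_tables(rng, 10, ["a", "b"], ["thickness", "area"])
        with pytest.raises(KeyError, match="available"):
            run_region_battery(tables, ["patient"] * 5 + ["control"] * 5,
                               ["a", "zzz"], B=10, seed=0)

    def test_empty_region_list_rejected(self, rng):
        tables = _noise_tables(rng, 10, ["a"], ["thickness", "area"])
        with pytest.raises(ValueError):
            run_region_battery(tables, ["patient"] * 5 + ["control"] * 5, [],
                               B=10, seed=0)


def test_rejection_rate_monotone_in_effect_size(rng):
    """Median rejection frequency never decreases along a d-grid."""
    grid = [0.0, 0.7, 1.4, 2.5]
    rates = []
    for d in grid:
        rejections = [
            permutation_test(rng.normal(d, 1, 20), rng.normal(0, 1, 20),
                             B=300, seed=i, exhaustive_threshold=0).p_value < 0.05
            for i in range(60)
        ]
        rates.append(np.mean(rejections))
    assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.95
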
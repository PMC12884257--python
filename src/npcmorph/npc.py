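"""Permutation tests and Fisher-method non-parametric combination (NPC).

The joint test for a region runs the same group-label shuffles across all
metrics (synchronized permutations preserve the cross-metric dependence of
thickness and area), converts each permuted statistic into a
within-permutation p-value by ranking it against the full permutation
distribution of its own metric, combines those p-values with Fisher's
T = -2*sum(ln p), and reads the joint empirical p off the permutation
distribution of T. Empirical p-values use the add-one convention
(r+1)/(B+1), which keeps them valid and strictly positive.

For small totals (n1+n2 <= exhaustive threshold) the Monte-Carlo shuffles
are replaced by complete enumeration of all C(n1+n2, n1) relabelings, in
which case p is exact (the observed labeling is one of the relabelings,
so no add-one smoothing is applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .group_stats import fdr_bh

StatKind = Literal["u", "mean_diff"]

__all__ = [
    "PermutationDistribution",
    "NPCResult",
    "permutation_test",
    "fisher_combine",
    "npc_joint",
    "run_region_battery",
    "RegionBatteryResult",
]

EXHAUSTIVE_THRESHOLD = 12


@dataclass
class PermutationDistribution:
    """Observed statistic with its permutation distribution."""

    observed: float
    permuted: np.ndarray
    n_permutations: int
    statistic: StatKind
    null_center: float
    p_value: float
    exhaustive: bool
    seed: int | None


@dataclass
class NPCResult:
    """Joint thickness+area (or any multi-metric) permutation test."""

    region: str
    metric_p: dict[str, float]
    fisher_statistic: float
    joint_p: float
    joint_p_adjusted: float | None = None


def _rank_u(ranks_x: np.ndarray) -> float:
    # U for the first sample from its pooled midranks
    n1 = len(ranks_x)
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def _permutation_indices(n: int, n1: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B random subsets of size n1 out of n, as a (B, n1) index array."""
    keys = rng.random((B, n))
    return np.argsort(keys, axis=1)[:, :n1]


def _exhaustive_indices(n: int, n1: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n1)), dtype=np.intp)


def _stat_over_assignments(
    pooled: np.ndarray, idx: np.ndarray, statistic: StatKind
) -> tuple[np.ndarray, float]:
    """Statistics for every label assignment plus the null center.

    The U statistic depends on the pooled midranks only, so ranks are
    computed once and summed per assignment — O(B * n1) after one sort.
    """
    n = len(pooled)
    n1 = idx.shape[1]
    n2 = n - n1
    if statistic == "u":
        ranks = stats.rankdata(pooled)
        vals = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        center = n1 * n2 / 2.0
    elif statistic == "mean_diff":
        total = pooled.sum()
        s1 = pooled[idx].sum(axis=1)
        vals = s1 / n1 - (total - s1) / n2
        center = 0.0
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return vals.astype(float), center


def permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    statistic: StatKind = "u",
    B: int = 5000,
    seed: int | None = None,
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
) -> PermutationDistribution:
    """Two-sided permutation test by group-label shuffling.

    Extremeness is distance from the statistic's null center (n1*n2/2 for
    U, 0 for the mean difference); both statistics are symmetric about
    their center under exchangeability.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])

    exhaustive = n1 + n2 <= exhaustive_threshold
    if exhaustive:
        idx = _exhaustive_indices(n1 + n2, n1)
    else:
        rng = np.random.default_rng(seed)
        idx = _permutation_indices(n1 + n2, n1, B, rng)

    vals, center = _stat_over_assignments(pooled, idx, statistic)
    obs_idx = np.arange(n1, dtype=np.intp)[None, :]
    observed = float(_stat_over_assignments(pooled, obs_idx, statistic)[0][0])

    dev_obs = abs(observed - center)
    dev = np.abs(vals - center)
    if exhaustive:
        p = float(np.count_nonzero(dev >= dev_obs - 1e-12) / len(vals))
    else:
        p = float((1 + np.count_nonzero(dev >= dev_obs - 1e-12)) / (B + 1))
    return PermutationDistribution(
        observed=observed, permuted=vals,
        n_permutations=len(vals) if exhaustive else B,
        statistic=statistic, null_center=center, p_value=p,
        exhaustive=exhaustive, seed=seed,
    )


def fisher_combine(p_list: Sequence[float]) -> float:
    """Fisher's combining statistic T = -2 * sum(ln p_i)."""
    p = np.asarray(p_list, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def _empirical_p_matrix(dev: np.ndarray) -> np.ndarray:
    """Within-permutation p for every permutation, add-one convention.

    dev: (B,) absolute deviations of one metric's permuted statistics.
    p_b = (1 + #{b': dev_b' >= dev_b}) / (B + 1), computed via one sort.
    """
    B = len(dev)
    order = np.sort(dev)
    # count of dev' >= dev_b  ==  B - (number strictly below dev_b)
    n_below = np.searchsorted(order, dev - 1e-12, side="left")
    return (1.0 + (B - n_below)) / (B + 1.0)


def npc_joint(
    x_metrics: Mapping[str, Sequence[float]],
    y_metrics: Mapping[str, Sequence[float]],
    B: int = 5000,
    seed: int | None = None,
    statistic: StatKind = "u",
    region: str = "",
) -> NPCResult:
    """Fisher-method NPC joint test across metrics of one region.

    The same label shuffles are applied to every metric; per-permutation
    p-values come from ranking each permuted statistic within its own
    metric's full permutation distribution.
    """
    metrics = list(x_metrics)
    if set(metrics) != set(y_metrics):
        raise ValueError("metric sets differ between groups")
    n1 = len(next(iter(x_metrics.values())))
    n2 = len(next(iter(y_metrics.values())))
    for m in metrics:
        if len(x_metrics[m]) != n1 or len(y_metrics[m]) != n2:
            raise ValueError(f"roster mismatch across metrics (metric {m!r})")

    rng = np.random.default_rng(seed)
    idx = _permutation_indices(n1 + n2, n1, B, rng)
    obs_idx = np.arange(n1, dtype=np.intp)[None, :]

    metric_p: dict[str, float] = {}
    t_obs_terms = []
    t_perm = np.zeros(B)
    for m in metrics:
        pooled = np.concatenate([np.asarray(x_metrics[m], float),
                                 np.asarray(y_metrics[m], float)])
        vals, center = _stat_over_assignments(pooled, idx, statistic)
        observed = float(_stat_over_assignments(pooled, obs_idx, statistic)[0][0])
        dev = np.abs(vals - center)
        dev_obs = abs(observed - center)
        p_obs = float((1 + np.count_nonzero(dev >= dev_obs - 1e-12)) / (B + 1))
        metric_p[m] = p_obs
        p_perm = _empirical_p_matrix(dev)
        t_obs_terms.append(-2.0 * math.log(p_obs))
        t_perm += -2.0 * np.log(p_perm)

    t_obs = float(sum(t_obs_terms))
    joint_p = float((1 + np.count_nonzero(t_perm >= t_obs - 1e-12)) / (B + 1))
    return NPCResult(region=region, metric_p=metric_p,
                     fisher_statistic=t_obs, joint_p=joint_p)


@dataclass
class RegionBatteryResult:
    """Per-metric permutation tests plus joint NPC tests over regions."""

    per_metric: "pd.DataFrame"  # region x metric rows: U, p, adjusted p
    npc: list[NPCResult]


def run_region_battery(
    tables: Mapping[str, "pd.DataFrame"],
    group_labels: Sequence[str],
    regions: Sequence[str],
    metrics: Sequence[str] | None = None,
    npc_metrics: Sequence[str] = ("thickness", "area"),
    B: int = 5000,
    seed: int | None = None,
    patient_label: str = "patient",
) -> RegionBatteryResult:
    """Regional battery: per region x metric permutation U tests with FDR
    within each metric across regions, plus Fisher-NPC joint tests (over
    ``npc_metrics``) with FDR across regions.

    ``tables`` maps metric name -> subjects x regions DataFrame, all on
    the same subject roster and order as ``group_labels``.
    """
    import pandas as pd

    if len(regions) == 0:
        raise ValueError("empty region list")
    metrics = list(metrics if metrics is not None else tables)
    labels = np.asarray(group_labels)
    is_x = labels == patient_label
    if is_x.sum() == 0 or (~is_x).sum() == 0:
        raise ValueError("both groups must be non-empty")

    for metric in metrics:
        avail = set(tables[metric].columns)
        missing = [r for r in regions if r not in avail]
        if missing:
            raise KeyError(
                f"unknown region(s) {missing} for metric {metric!r}; "
                f"available: {sorted(avail)}"
            )

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(regions) * len(metrics) + len(regions))
    child_iter = iter(children)

    rows = []
    for metric in metrics:
        for region in regions:
            vals = tables[metric][region].to_numpy(dtype=float)
            sub_seed = int(next(child_iter).generate_state(1)[0] % (2**31))
            dist = permutation_test(vals[is_x], vals[~is_x], statistic="u",
                                    B=B, seed=sub_seed,
                                    exhaustive_threshold=0)
            rows.append({"region": region, "metric": metric,
                         "U": dist.observed, "p": dist.p_value})
    per_metric = pd.DataFrame(rows)
    per_metric["p_adjusted"] = np.nan
    for metric in metrics:
        mask = per_metric["metric"] == metric
        per_metric.loc[mask, "p_adjusted"] = fdr_bh(per_metric.loc[mask, "p"].to_numpy())

    npc_results = []
    for region in regions:
        sub_seed = int(next(child_iter).generate_state(1)[0] % (2**31))
        x_m = {m: tables[m][region].to_numpy(float)[is_x] for m in npc_metrics}
        y_m = {m: tables[m][region].to_numpy(float)[~is_x] for m in npc_metrics}
        npc_results.append(npc_joint(x_m, y_m, B=B, seed=sub_seed, region=region))
    joint_adj = fdr_bh([r.joint_p for r in npc_results])
    for res, adj in zip(npc_results, joint_adj):
        res.joint_p_adjusted = float(adj)

    return RegionBatteryResult(per_metric=per_metric, npc=npc_results)
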
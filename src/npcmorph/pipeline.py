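"""Config-driven orchestration of the full analysis sequence.

Stages, in the order a clinical morphometry report presents them:

1. clinical/psychological group comparisons (gated t/U tests, FDR);
2. global volume battery (permutation U tests, FDR);
3. regional per-metric permutation tests and Fisher-NPC joint tests
   over the a-priori regions (FDR within metric and across regions);
4. Kendall tau-b correlation screen over questionnaires, BMI-SDS and
   every region x metric whose adjusted group difference cleared alpha;
5. backward-elimination regression predicting the headline region's
   thickness;
6. Monte Carlo power per scenario plus the analytic minimum detectable
   effect size;
7. optional exploratory battery over all regions in the tables, with
   its own correlation screen.

Every stage is seeded-deterministic; outputs are TSV tables named after
their report-table analogues plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import LMSReference, bmi_sds, correlation_screen
from .group_stats import compare_groups, fdr_bh
from .io import MorphometryTable, combine_hemispheres, read_metadata, read_stats_table
from .npc import run_region_battery
from .power import MDESQuery, mc_power, min_detectable_d
from .regression import backward_eliminate
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort

__all__ = ["AnalysisConfig", "RunManifest", "run_pipeline", "load_config"]

DEFAULT_QUESTIONNAIRE_COLUMNS = (
    "EDI_II", "BAI", "BDI_II", "PAQ", "BPQ_A", "BPQ_supra", "BPQ_sub")
DEFAULT_PREDICTORS = (
    "age", "bmi_sds", "BAI", "BPQ_A", "BPQ_supra", "BPQ_sub",
    "PAQ_NDIF", "PAQ_PDIF", "PAQ_NDDF", "PAQ_PDDF", "PAQ_EOT",
    "EDI_DT", "EDI_P", "EDI_MF", "EDI_SI", "EDI_ID", "EDI_IN")


@dataclass
class AnalysisConfig:
    """Everything a pipeline run depends on, with report defaults."""

    # either a directory of stats tables + metadata (+ LMS) ...
    input_dir: str | None = None
    # ... or a synthetic cohort spec (dict of CohortSpec overrides)
    synthetic: dict | None = None

    regions: tuple[str, ...] = (
        "caudalanteriorcingulate", "rostralanteriorcingulate",
        "posteriorcingulate", "isthmuscingulate", "precuneus")
    metrics: tuple[str, ...] = ("thickness", "area", "volume")
    npc_metrics: tuple[str, ...] = ("thickness", "area")
    questionnaires: tuple[str, ...] = DEFAULT_QUESTIONNAIRE_COLUMNS
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    outcome_region: str = "precuneus"

    n_permutations: int = 5000
    n_sim: int = 600
    n_perm: int = 1200
    alpha: float = 0.05
    p_out: float = 0.10
    p_in: float = 0.05
    power_metric: str = "thickness"
    exploratory: bool = False
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            # synthetic defaults are still a valid run
            pass
        if len(self.regions) == 0:
            raise ValueError("region list must not be empty")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_sim < 1 or self.n_perm < 1:
            raise ValueError("n_sim and n_perm must be >= 1")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, files: list[str], rows: int, seconds: float) -> None:
        self.stages[stage] = {"files": files, "rows": rows,
                              "seconds": round(seconds, 3)}

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig(**raw)
    for name in ("regions", "metrics", "npc_metrics", "questionnaires", "predictors"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    return cfg


def _load_inputs(cfg: AnalysisConfig):
    """Return (tables: metric -> combined DataFrame, aseg table, metadata, lms)."""
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        tables = {}
        for metric in cfg.metrics:
            left = read_stats_table(d / f"lh.aparc.{metric}.tsv", metric, "left")
            right = read_stats_table(d / f"rh.aparc.{metric}.tsv", metric, "right")
            tables[metric] = combine_hemispheres(left, right)
        aseg = read_stats_table(d / "aseg.volume.tsv", "volume", "none")
        meta = read_metadata(d / "metadata.tsv")
        lms_path = d / "lms_reference_synthetic.tsv"
        lms = LMSReference.from_tsv(lms_path) if lms_path.exists() else None
        return tables, aseg, meta, lms

    overrides = dict(cfg.synthetic or {})
    overrides.setdefault("seed", cfg.seed)
    if "region_effects" in overrides:
        overrides["region_effects"] = {
            (r, m): v for (r, m), v in overrides["region_effects"].items()}
    spec = CohortSpec(**overrides)
    cohort = generate_cohort(spec)
    return cohort.morphometry, cohort.aseg, cohort.metadata, cohort.lms_reference


def _comparison_table(meta: pd.DataFrame, variables, family: str) -> pd.DataFrame:
    is_p = meta["group"] == "patient"
    rows = []
    for var in variables:
        x = meta.loc[is_p, var].to_numpy(float)
        y = meta.loc[~is_p, var].to_numpy(float)
        res = compare_groups(x, y, variable=var, family=family)
        rows.append({
            "variable": var, "test": res.test_kind, "statistic": res.statistic,
            "p": res.p_raw, "effect_size": res.effect_size,
            "effect_kind": "r" if res.test_kind == "mann_whitney" else "d",
        })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = fdr_bh(out["p"].to_numpy())
    return out


def run_pipeline(cfg: AnalysisConfig) -> RunManifest:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=cfg.seed, version=__version__)
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    tables_mt, aseg, meta, lms = _load_inputs(cfg)
    tables = {m: (t.values if isinstance(t, MorphometryTable) else t)
              for m, t in tables_mt.items()}
    meta = meta.loc[[s for s in meta.index if s in tables[cfg.metrics[0]].index]]
    labels = meta["group"].to_numpy()

    # recompute BMI-SDS through the LMS reference when one is available
    if lms is not None and "bmi" in meta.columns:
        meta = meta.copy()
        meta["bmi_sds"] = [
            bmi_sds(b, a, s, lms)
            for b, a, s in zip(meta["bmi"], meta["age"], meta["sex"])]

    # -- stage 1: clinical/psychological comparisons ----------------------
    t0 = time.perf_counter()
    clin_vars = ["age", "bmi_sds", *[q for q in cfg.questionnaires if q in meta.columns]]
    table1 = _comparison_table(meta, clin_vars, family="clinical")
    p1 = out / "table1_clinical.tsv"
    table1.to_csv(p1, sep="\t", index=False)
    manifest.record("clinical_comparisons", [p1.name], len(table1), time.perf_counter() - t0)

    # -- stage 2: global volume battery -----------------------------------
    t0 = time.perf_counter()
    aseg_df = aseg.values if isinstance(aseg, MorphometryTable) else aseg
    aseg_df = aseg_df.loc[meta.index]
    battery_g = run_region_battery(
        {"volume": aseg_df}, labels, regions=list(aseg_df.columns),
        metrics=["volume"], npc_metrics=("volume",),
        B=cfg.n_permutations, seed=stage_seeds[1])
    table3 = battery_g.per_metric.drop(columns="metric")
    p3 = out / "table3_global_volumes.tsv"
    table3.to_csv(p3, sep="\t", index=False)
    manifest.record("global_volumes", [p3.name], len(table3), time.perf_counter() - t0)

    # -- stage 3+4: regional permutation tests and NPC ---------------------
    t0 = time.perf_counter()
    tables_aligned = {m: df.loc[meta.index] for m, df in tables.items()}
    battery = run_region_battery(
        tables_aligned, labels, regions=list(cfg.regions),
        metrics=list(cfg.metrics), npc_metrics=cfg.npc_metrics,
        B=cfg.n_permutations, seed=stage_seeds[2])
    npc_rows = [{
        "region": r.region,
        **{f"p_{m}": p for m, p in r.metric_p.items()},
        "fisher_statistic": r.fisher_statistic,
        "joint_p": r.joint_p, "joint_p_adjusted": r.joint_p_adjusted,
    } for r in battery.npc]
    table4 = pd.DataFrame(npc_rows)
    p4 = out / "table4_npc.tsv"
    table4.to_csv(p4, sep="\t", index=False)
    p4m = out / "table4_per_metric.tsv"
    battery.per_metric.to_csv(p4m, sep="\t", index=False)
    manifest.record("regional_npc", [p4.name, p4m.name],
                    len(table4) + len(battery.per_metric), time.perf_counter() - t0)

    # -- stage 5: correlation screen --------------------------------------
    t0 = time.perf_counter()
    sig = battery.per_metric[battery.per_metric["p_adjusted"] < cfg.alpha]
    screen_cols = meta[[q for q in cfg.questionnaires if q in meta.columns]].copy()
    screen_cols["bmi_sds"] = meta["bmi_sds"]
    for _, row in sig.iterrows():
        name = f"{row['region']}_{row['metric']}"
        screen_cols[name] = tables_aligned[row["metric"]][row["region"]]
    table5 = correlation_screen(screen_cols, family="primary_screen")
    p5 = out / "table5_correlations.tsv"
    stacked = pd.concat(
        [table5.tau.stack().rename("tau"),
         table5.p_raw.stack().rename("p"),
         table5.p_adjusted.stack().rename("p_adjusted")], axis=1)
    stacked.index.names = ["var1", "var2"]
    stacked.reset_index().to_csv(p5, sep="\t", index=False)
    manifest.record("correlation_screen", [p5.name], len(stacked), time.perf_counter() - t0)

    # -- stage 6: backward-elimination regression --------------------------
    t0 = time.perf_counter()
    y = tables_aligned["thickness"][cfg.outcome_region]
    predictors = [p for p in cfg.predictors if p in meta.columns]
    X = meta[predictors].astype(float)
    model = backward_eliminate(y, X, p_out=cfg.p_out, p_in=cfg.p_in)
    table6 = model.coefficients.copy()
    table6.insert(0, "predictor", table6.index)
    table6["adj_R2"] = model.adj_r_squared
    p6 = out / "table6_regression.tsv"
    table6.to_csv(p6, sep="\t", index=False)
    manifest.record("regression", [p6.name], len(table6), time.perf_counter() - t0)

    # -- stage 7: power -----------------------------------------------------
    t0 = time.perf_counter()
    is_p = labels == "patient"
    rows = []
    metric = cfg.power_metric
    for region in cfg.regions:
        vals = tables_aligned[metric][region].to_numpy(float)
        x, yv = vals[is_p], vals[~is_p]
        sd_pool = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(yv) - 1) * yv.var(ddof=1))
                          / (len(x) + len(yv) - 2))
        d_obs = (x.mean() - yv.mean()) / sd_pool
        est = mc_power(n1=len(x), n2=len(yv), d=float(d_obs),
                       n_sim=cfg.n_sim, n_perm=cfg.n_perm, alpha=cfg.alpha,
                       seed=stage_seeds[5], label=f"{region}_{metric}")
        rows.append({"scenario": est.label, "d": float(d_obs), "power": est.rate,
                     "se": est.se, "n_sim": est.n_sim, "n_perm": est.n_perm})
    table7 = pd.DataFrame(rows)
    mdes = min_detectable_d(MDESQuery(int(is_p.sum()), int((~is_p).sum()),
                                      cfg.alpha, 0.80))
    table7["min_detectable_d"] = mdes
    p7 = out / "table7_power.tsv"
    table7.to_csv(p7, sep="\t", index=False)
    manifest.record("power", [p7.name], len(table7), time.perf_counter() - t0)

    # -- stage 8: exploratory battery --------------------------------------
    if cfg.exploratory:
        t0 = time.perf_counter()
        all_regions = list(tables_aligned[cfg.metrics[0]].columns)
        explo = run_region_battery(
            tables_aligned, labels, regions=all_regions,
            metrics=list(cfg.metrics), npc_metrics=cfg.npc_metrics,
            B=cfg.n_permutations, seed=stage_seeds[6])
        p9 = out / "table9_exploratory.tsv"
        explo.per_metric.to_csv(p9, sep="\t", index=False)
        sig_e = explo.per_metric[explo.per_metric["p_adjusted"] < cfg.alpha]
        files = [p9.name]
        n_rows = len(explo.per_metric)
        if len(sig_e):
            cols = meta[[q for q in cfg.questionnaires if q in meta.columns]].copy()
            cols["bmi_sds"] = meta["bmi_sds"]
            for _, row in sig_e.iterrows():
                cols[f"{row['region']}_{row['metric']}"] = (
                    tables_aligned[row["metric"]][row["region"]])
            screen_e = correlation_screen(cols, family="exploratory_screen")
            p10 = out / "table10_exploratory_correlations.tsv"
            pd.concat([screen_e.tau.stack().rename("tau"),
                       screen_e.p_raw.stack().rename("p"),
                       screen_e.p_adjusted.stack().rename("p_adjusted")],
                      axis=1).reset_index().to_csv(p10, sep="\t", index=False)
            files.append(p10.name)
        manifest.record("exploratory", files, n_rows, time.perf_counter() - t0)

    manifest.to_json(out / "run_manifest.json")
    return manifest
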
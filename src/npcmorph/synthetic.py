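"""Synthetic cohort generator emulating an adolescent two-group
ROI-morphometry study.

The generator reproduces the statistical structure the downstream
analyses assume, so every stage is testable without access to clinical
data:

* two groups (default 26 patients, 24 controls) of female adolescents;
* per-region thickness / surface-area / volume values, Gaussian in
  native units, with configurable standardized group effects (the
  default injects a focal thickness deficit in the precuneus) and a
  within-region correlation between a subject's thickness and area
  deviations;
* questionnaire batteries driven by a single latent severity factor
  (group-shifted), discretized to integers and clipped to instrument
  ranges — producing the heavy ties that exercise tie-corrected rank
  statistics;
* BMI-SDS negatively loaded on severity, with raw BMI recovered through
  the inverse LMS transform of a bundled synthetic growth reference.

One global seed feeds splittable per-table streams keyed by a stable
hash of the table name, so adding a region or questionnaire does not
perturb any other table's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import LMSReference, bmi_from_sds, synthetic_lms_reference
from .io import MorphometryTable, write_stats_table

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "write_cohort",
           "APRIORI_REGIONS", "DEFAULT_QUESTIONNAIRES"]

#: a-priori cingulate/precuneus regions of the primary analysis
APRIORI_REGIONS = (
    "caudalanteriorcingulate",
    "rostralanteriorcingulate",
    "posteriorcingulate",
    "isthmuscingulate",
    "precuneus",
)

#: questionnaire -> (min, max, integer-valued) score ranges
DEFAULT_QUESTIONNAIRES: dict[str, tuple[float, float, bool]] = {
    "EDI_II": (64, 384, True),
    "BAI": (0, 63, True),
    "BDI_II": (0, 63, True),
    "PAQ": (0, 144, True),
    "BPQ_A": (26, 130, True),
    "BPQ_supra": (15, 75, True),
    "BPQ_sub": (6, 30, True),
    # subscales used as regression predictors
    "EDI_DT": (0, 30, True),
    "EDI_P": (0, 30, True),
    "EDI_MF": (0, 30, True),
    "EDI_SI": (0, 30, True),
    "EDI_ID": (0, 30, True),
    "EDI_IN": (0, 30, True),
    "PAQ_NDIF": (0, 30, True),
    "PAQ_PDIF": (0, 30, True),
    "PAQ_NDDF": (0, 30, True),
    "PAQ_PDDF": (0, 30, True),
    "PAQ_EOT": (0, 30, True),
}

#: native-unit (mean, sd) baselines per cortical region and metric
_DEFAULT_BASELINES: dict[tuple[str, str], tuple[float, float]] = {}
for _r, _area_mu, _vol_mu in (
    ("caudalanteriorcingulate", 700.0, 1900.0),
    ("rostralanteriorcingulate", 850.0, 2500.0),
    ("posteriorcingulate", 1100.0, 3000.0),
    ("isthmuscingulate", 950.0, 2500.0),
    ("precuneus", 3600.0, 9800.0),
):
    _DEFAULT_BASELINES[(_r, "thickness")] = (2.5, 0.15)
    _DEFAULT_BASELINES[(_r, "area")] = (_area_mu, 0.10 * _area_mu)
    _DEFAULT_BASELINES[(_r, "volume")] = (_vol_mu, 0.11 * _vol_mu)

#: aseg-style global/subcortical volume baselines (mm^3)
DEFAULT_GLOBAL_VOLUMES: dict[str, tuple[float, float]] = {
    "TotalGrayVol": (700_000.0, 55_000.0),
    "CerebralWhiteMatterVol": (420_000.0, 40_000.0),
    "SubCortGrayVol": (60_000.0, 4_500.0),
    "CortexVol": (520_000.0, 45_000.0),
    "CerebellumCortexVol": (110_000.0, 10_000.0),
    "CerebellumWhiteMatterVol": (28_000.0, 3_000.0),
    "Hippocampus": (8_300.0, 700.0),
    "Amygdala": (3_300.0, 320.0),
    "BrainStem": (20_000.0, 1_900.0),
}


@dataclass
class CohortSpec:
    """Generating parameters of a synthetic two-group cohort."""

    n_patient: int = 26
    n_control: int = 24
    regions: tuple[str, ...] = APRIORI_REGIONS
    # standardized patient-minus-control difference per (region, metric)
    region_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("precuneus", "thickness"): -1.1})
    metric_baselines: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES))
    global_volumes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_VOLUMES))
    global_volume_effects: dict[str, float] = field(default_factory=dict)
    thickness_area_corr: float = 0.3
    severity_loadings: dict[str, float] = field(
        default_factory=lambda: {q: 0.8 for q in DEFAULT_QUESTIONNAIRES})
    severity_group_shift: float = 2.0
    bmi_sds_loading: float = -0.7
    score_ranges: dict[str, tuple[float, float, bool]] = field(
        default_factory=lambda: dict(DEFAULT_QUESTIONNAIRES))
    age_range: tuple[float, float] = (12.0, 19.0)
    hemi_asymmetry: float = 0.05  # hemisphere noise as a fraction of the region sd
    seed: int = 0

    def validate(self) -> None:
        if self.n_patient < 2:
            raise ValueError("n_patient must be >= 2")
        if self.n_control < 2:
            raise ValueError("n_control must be >= 2")
        for key, (mu, sd) in self.metric_baselines.items():
            if sd <= 0:
                raise ValueError(f"metric_baselines[{key}]: sd must be positive")
        for name, (mu, sd) in self.global_volumes.items():
            if sd <= 0:
                raise ValueError(f"global_volumes[{name!r}]: sd must be positive")
        if not -1.0 <= self.thickness_area_corr <= 1.0:
            raise ValueError("thickness_area_corr must lie in [-1, 1]")
        for q, loading in self.severity_loadings.items():
            if not 0.0 <= loading <= 1.0:
                raise ValueError(f"severity_loadings[{q!r}] must lie in [0, 1]")
            if q not in self.score_ranges:
                raise ValueError(f"severity_loadings names unknown questionnaire {q!r}")
        if not -1.0 <= self.bmi_sds_loading <= 1.0:
            raise ValueError("bmi_sds_loading must lie in [-1, 1]")
        for q, (lo, hi, _) in self.score_ranges.items():
            if not lo < hi:
                raise ValueError(f"score_ranges[{q!r}]: min must be < max")
        for region, metric in self.region_effects:
            if (region, metric) not in self.metric_baselines:
                raise ValueError(f"region_effects names unknown table {(region, metric)!r}")


@dataclass
class SyntheticCohort:
    """Generated cohort: combined-hemisphere tables, hemisphere tables,
    an aseg-style global-volume table, metadata, and the generating spec."""

    morphometry: dict[str, MorphometryTable]          # metric -> combined table
    hemispheres: dict[tuple[str, str], MorphometryTable]  # (metric, hemi) -> table
    aseg: MorphometryTable                            # global/subcortical volumes
    metadata: pd.DataFrame                            # CohortFrame (index: subject)
    lms_reference: LMSReference
    truth: CohortSpec

    @property
    def group_labels(self) -> np.ndarray:
        return self.metadata["group"].to_numpy()


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent per-table stream keyed by a stable hash of ``name``."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _round6(df: pd.DataFrame) -> pd.DataFrame:
    # values live at the precision the TSV writer prints, so write/read
    # round-trips are bit-identical
    return df.round(6)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from ``spec``. Deterministic given ``spec.seed``."""
    spec.validate()
    n = spec.n_patient + spec.n_control
    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    is_patient = np.array([True] * spec.n_patient + [False] * spec.n_control)
    group = np.where(is_patient, "patient", "control")

    # ---- metadata -------------------------------------------------------
    rng_meta = _stream(spec.seed, "meta/age")
    lo, hi = spec.age_range
    age = np.clip(rng_meta.normal((lo + hi) / 2 - 0.4, 1.6, n), lo, hi).round(2)

    rng_sev = _stream(spec.seed, "meta/severity")
    severity = rng_sev.normal(0.0, 1.0, n) + spec.severity_group_shift * is_patient

    meta = pd.DataFrame({"group": group, "age": age, "sex": "f"}, index=subjects)
    meta.index.name = "subject"

    lms = synthetic_lms_reference()
    rng_bmi = _stream(spec.seed, "meta/bmi_sds")
    l_b = spec.bmi_sds_loading
    sds = l_b * severity + np.sqrt(max(0.0, 1 - l_b**2)) * rng_bmi.normal(0, 1, n)
    sds = np.clip(sds, -4.0, 4.0).round(4)
    bmi = np.array([bmi_from_sds(z, a, "f", lms) for z, a in zip(sds, age)]).round(2)
    meta["bmi"] = bmi
    meta["bmi_sds"] = sds

    for q, (lo_q, hi_q, integer) in spec.score_ranges.items():
        loading = spec.severity_loadings.get(q, 0.0)
        rng_q = _stream(spec.seed, f"meta/q/{q}")
        latent = loading * severity + np.sqrt(max(0.0, 1 - loading**2)) * rng_q.normal(0, 1, n)
        # control group centred in the lower third of the range; unit
        # latent SD maps to an eighth of the range so shifted patients
        # rarely clip
        center = lo_q + 0.30 * (hi_q - lo_q)
        scale = (hi_q - lo_q) / 8.0
        score = center + scale * latent
        score = np.clip(np.round(score) if integer else score, lo_q, hi_q)
        meta[q] = score.astype(int) if integer else score

    # ---- cortical morphometry ------------------------------------------
    metrics = sorted({m for (_, m) in spec.metric_baselines})
    combined: dict[str, dict[str, np.ndarray]] = {m: {} for m in metrics}
    hemi_vals: dict[tuple[str, str], dict[str, np.ndarray]] = {
        (m, h): {} for m in metrics for h in ("left", "right")}

    for region in spec.regions:
        rng_r = _stream(spec.seed, f"morph/{region}")
        rho = spec.thickness_area_corr
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z_ta = rng_r.multivariate_normal([0.0, 0.0], cov, size=n)
        z = {"thickness": z_ta[:, 0], "area": z_ta[:, 1],
             "volume": rng_r.normal(0, 1, n)}
        for metric in metrics:
            if (region, metric) not in spec.metric_baselines:
                continue
            mu, sd = spec.metric_baselines[(region, metric)]
            d = spec.region_effects.get((region, metric), 0.0)
            vals = mu + sd * (z[metric] + d * is_patient)
            vals = np.maximum(vals, 1e-6)
            asym = rng_r.normal(0, spec.hemi_asymmetry * sd, n)
            if metric == "volume":
                left, right = vals / 2 + asym, vals / 2 - asym
            else:
                left, right = vals + asym, vals - asym
            combined[metric][region] = vals
            hemi_vals[(metric, "left")][region] = np.maximum(left, 1e-6)
            hemi_vals[(metric, "right")][region] = np.maximum(right, 1e-6)

    def _table(data: dict[str, np.ndarray], metric: str, hemi: str,
               extras: pd.DataFrame | None = None) -> MorphometryTable:
        df = _round6(pd.DataFrame(data, index=subjects))
        df.index.name = "subject"
        return MorphometryTable(values=df, metric=metric, hemisphere=hemi,
                                extras=extras if extras is not None else pd.DataFrame(index=df.index))

    morph = {m: _table(combined[m], m, "combined") for m in metrics if combined[m]}
    hemis = {(m, h): _table(hemi_vals[(m, h)], m, h)
             for m in metrics for h in ("left", "right") if hemi_vals[(m, h)]}

    # ---- aseg-style global volumes -------------------------------------
    aseg_data = {}
    for name, (mu, sd) in spec.global_volumes.items():
        rng_g = _stream(spec.seed, f"aseg/{name}")
        d = spec.global_volume_effects.get(name, 0.0)
        aseg_data[name] = np.maximum(mu + sd * (rng_g.normal(0, 1, n) + d * is_patient), 1.0)
    rng_icv = _stream(spec.seed, "aseg/eTIV")
    etiv = rng_icv.normal(1.45e6, 1.1e5, n)
    extras = _round6(pd.DataFrame({"EstimatedTotalIntraCranialVol": etiv}, index=subjects))
    aseg = _table(aseg_data, "volume", "none", extras=extras)

    return SyntheticCohort(morphometry=morph, hemispheres=hemis, aseg=aseg,
                           metadata=meta, lms_reference=lms, truth=spec)


def write_cohort(cohort: SyntheticCohort, directory) -> list[Path]:
    """Write the cohort as stats-table TSVs plus metadata and LMS TSVs.

    File layout mirrors aparcstats2table/asegstats2table exports:
    ``lh.aparc.<metric>.tsv`` / ``rh.aparc.<metric>.tsv`` per cortical
    metric, ``aseg.volume.tsv`` for globals, ``metadata.tsv``, and the
    synthetic LMS reference.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (metric, hemi), table in sorted(cohort.hemispheres.items()):
        prefix = {"left": "lh", "right": "rh"}[hemi]
        path = directory / f"{prefix}.aparc.{metric}.tsv"
        write_stats_table(table, path)
        written.append(path)
    path = directory / "aseg.volume.tsv"
    write_stats_table(cohort.aseg, path)
    written.append(path)

    meta_path = directory / "metadata.tsv"
    cohort.metadata.to_csv(meta_path, sep="\t")
    written.append(meta_path)

    lms_path = directory / "lms_reference_synthetic.tsv"
    cohort.lms_reference.to_tsv(lms_path)
    written.append(lms_path)
    return written
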
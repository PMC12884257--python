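"""Reading FreeSurfer-style ROI statistics tables and hemisphere rules.

``aparcstats2table`` / ``asegstats2table`` emit plain-text tables: first
column the subject identifier (its header names the table, e.g.
``lh.aparc.thickness``), one numeric column per region. Cortical column
names carry a hemisphere prefix (``lh_``/``rh_``) and a metric suffix
(``_thickness``/``_area``/``_volume``); summary columns such as eTIV,
MeanThickness or WhiteSurfArea are recognized and set aside.

Hemisphere combination follows ROI-morphometry convention: volumes are
summed across hemispheres, thickness and surface area are averaged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MorphometryTable",
    "read_stats_table",
    "write_stats_table",
    "combine_hemispheres",
    "normalize_to_icv",
    "read_metadata",
    "validate_cohort_frame",
]

METRICS = ("thickness", "area", "volume")
HEMIS = ("left", "right", "combined", "none")

#: aparcstats2table / asegstats2table summary columns that are not regions
_EXTRA_PATTERNS = re.compile(
    r"(MeanThickness|WhiteSurfArea|eTIV|EstimatedTotalIntraCranialVol|BrainSegVol)",
    re.IGNORECASE,
)
_HEMI_PREFIX = {"lh": "left", "rh": "right"}


@dataclass
class MorphometryTable:
    """Subjects x regions matrix of one morphometric metric."""

    values: pd.DataFrame  # index: subject id, columns: region names
    metric: str
    hemisphere: str
    extras: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.hemisphere not in HEMIS:
            raise ValueError(f"hemisphere must be one of {HEMIS}, got {self.hemisphere!r}")
        if self.values.isna().any().any():
            raise ValueError("missing cells after ingestion (complete-case required)")
        if (self.values.to_numpy(float) < 0).any():
            raise ValueError("morphometry values must be non-negative")
        if self.metric == "thickness":
            vals = self.values.to_numpy(float)
            bad = (vals <= 0) | (vals >= 10)
            if bad.any():
                logger.warning(
                    "%d thickness values outside the plausible (0, 10) mm range",
                    int(bad.sum()),
                )

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else r"\s+"


def _canonical_region(col: str, metric: str) -> tuple[str, str | None]:
    """Strip hemisphere prefix and metric suffix from a column name."""
    hemi = None
    for prefix, name in _HEMI_PREFIX.items():
        if col.startswith(prefix + "_"):
            hemi = name
            col = col[len(prefix) + 1:]
            break
    for suffix in METRICS:
        if col.endswith("_" + suffix):
            col = col[: -(len(suffix) + 1)]
            break
    return col, hemi


def read_stats_table(path, metric: str, hemisphere: str = "none") -> MorphometryTable:
    """Read one aparcstats2table/asegstats2table-style text file.

    Region columns are renamed to canonical region names (prefix/suffix
    stripped); recognized summary columns go to ``.extras``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep=_sniff_sep(header))
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no subject rows")
    subject_col = df.columns[0]
    df = df.rename(columns={subject_col: "subject"})
    if df["subject"].duplicated().any():
        dup = df.loc[df["subject"].duplicated(), "subject"].iloc[0]
        raise ValueError(f"{path}: duplicate subject id {dup!r}")
    df = df.set_index("subject")
    df.index = df.index.astype(str)

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")

    extras_cols = [c for c in df.columns if _EXTRA_PATTERNS.search(c)]
    extras = df[extras_cols].copy()
    regions = df.drop(columns=extras_cols)

    renames = {}
    for col in regions.columns:
        name, col_hemi = _canonical_region(col, metric)
        if col_hemi is not None and hemisphere == "none":
            hemisphere = col_hemi
        renames[col] = name
    regions = regions.rename(columns=renames)
    return MorphometryTable(values=regions.astype(float), metric=metric,
                            hemisphere=hemisphere, extras=extras)


def write_stats_table(table: MorphometryTable, path) -> None:
    """Write back in the same dialect ``read_stats_table`` accepts."""
    prefix = {"left": "lh", "right": "rh"}.get(table.hemisphere)
    df = table.values.copy()
    if prefix is not None:
        df.columns = [f"{prefix}_{c}_{table.metric}" for c in df.columns]
    for col in table.extras.columns:
        df[col] = table.extras[col]
    first_col = (f"{prefix}.aparc.{table.metric}" if prefix is not None
                 else f"Measure:{table.metric}")
    df.index.name = first_col
    df.to_csv(path, sep="\t", float_format="%.6f")


def combine_hemispheres(left: MorphometryTable, right: MorphometryTable) -> MorphometryTable:
    """Sum volumes across hemispheres; average thickness and area."""
    if left.metric != right.metric:
        raise ValueError(f"metric mismatch: {left.metric} vs {right.metric}")
    if {left.hemisphere, right.hemisphere} != {"left", "right"}:
        raise ValueError("inputs must be one left and one right table")
    if left.subjects != right.subjects or left.regions != right.regions:
        raise ValueError("subject/region roster mismatch between hemispheres")
    if left.metric == "volume":
        combined = left.values + right.values
    else:
        combined = (left.values + right.values) / 2.0
    return MorphometryTable(values=combined, metric=left.metric, hemisphere="combined")


def normalize_to_icv(table: MorphometryTable, icv: pd.Series) -> MorphometryTable:
    """Divide each subject's volumes by intracranial volume (fractions)."""
    if table.metric != "volume":
        raise ValueError("ICV normalization applies to volume tables only")
    icv = icv.reindex(table.values.index)
    if icv.isna().any():
        missing = list(icv[icv.isna()].index)
        raise ValueError(f"missing ICV for subjects {missing}")
    if (icv <= 0).any():
        raise ValueError("ICV must be positive for all subjects")
    return MorphometryTable(values=table.values.div(icv, axis=0),
                            metric="volume", hemisphere=table.hemisphere)


def read_metadata(path) -> pd.DataFrame:
    """Read the per-subject metadata table (group, age, sex, BMI, scores)."""
    df = pd.read_csv(path, sep="\t")
    df["subject"] = df["subject"].astype(str)
    return validate_cohort_frame(df.set_index("subject"))


def validate_cohort_frame(frame: pd.DataFrame,
                          tables: list[MorphometryTable] | None = None) -> pd.DataFrame:
    """Enforce the cohort-frame contract; optionally align to tables.

    Subjects absent from any morphometry table are dropped with a warning
    (complete-case ingestion).
    """
    if "group" not in frame.columns:
        raise ValueError("metadata must contain a 'group' column")
    levels = frame["group"].unique()
    if len(levels) != 2:
        raise ValueError(f"group must have exactly two levels, found {sorted(levels)}")
    if "age" in frame.columns and (frame["age"] <= 0).any():
        raise ValueError("ages must be positive")
    if tables:
        common = set(frame.index)
        for t in tables:
            common &= set(t.subjects)
        dropped = sorted(set(frame.index) - common)
        if dropped:
            logger.warning("dropping %d subject(s) missing from some table: %s",
                           len(dropped), dropped)
            frame = frame.loc[[s for s in frame.index if s in common]]
    return frame
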
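#!/usr/bin/env python
"""Exploratory whole-table battery with its correlation screen.

Runs the per-metric permutation battery over every cortical region in
the stats tables (here the full generated set), FDR within metric, then
correlates FDR-significant region x metric values with the
questionnaire totals and BMI-SDS. Writes results/table9_exploratory.tsv
and, when anything survives, results/table10_exploratory_correlations.tsv.
"""

from pathlib import Path

import pandas as pd

from npcmorph.association import correlation_screen
from npcmorph.io import read_metadata
from npcmorph.npc import run_region_battery

from analysis_io import load_metric_column

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "regional", Path(__file__).with_name("04_regional_npc.py"))
_regional = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_regional)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 81
QUESTIONNAIRES = ("EDI_II", "BAI", "BDI_II", "PAQ", "BPQ_A", "BPQ_supra", "BPQ_sub")


def main() -> None:
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    tables = _regional.load_tables(meta.index)
    regions = list(tables["thickness"].columns)
    battery = run_region_battery(
        tables, meta["group"].to_numpy(), regions=regions,
        metrics=list(tables), B=5000, seed=SEED)
    battery.per_metric.to_csv(ROOT / "table9_exploratory.tsv", sep="\t", index=False)
    flagged = battery.per_metric[battery.per_metric["p_adjusted"] < 0.05]
    print(battery.per_metric.to_string(index=False))
    print(f"\n{len(flagged)} region x metric cells survive within-metric FDR")

    if len(flagged):
        frame = meta[list(QUESTIONNAIRES)].copy()
        frame["bmi_sds"] = meta["bmi_sds"]
        for _, row in flagged.iterrows():
            frame[f"{row['region']}_{row['metric']}"] = load_metric_column(
                ROOT / "cohort", row["metric"], row["region"], meta.index)
        screen = correlation_screen(frame, family="exploratory_screen")
        stacked = pd.concat([screen.tau.stack().rename("tau"),
                             screen.p_raw.stack().rename("p"),
                             screen.p_adjusted.stack().rename("p_adjusted")], axis=1)
        stacked.index.names = ["var1", "var2"]
        stacked.reset_index().to_csv(
            ROOT / "table10_exploratory_correlations.tsv", sep="\t", index=False)
        print("wrote table10_exploratory_correlations.tsv")
    print("wrote table9_exploratory.tsv")


if __name__ == "__main__":
    main()
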
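#!/usr/bin/env python
"""Kendall tau-b correlation screen.

BMI-SDS is recomputed from raw BMI through the bundled synthetic LMS
reference, then all pairwise tau-b correlations are taken over the
questionnaire totals, BMI-SDS and every region x metric that cleared
the FDR battery in step 04 (one FDR family over the unique pairs).
Writes results/table5_correlations.tsv.
"""

from pathlib import Path

import pandas as pd

from npcmorph.association import LMSReference, bmi_sds, correlation_screen
from npcmorph.io import read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"
QUESTIONNAIRES = ("EDI_II", "BAI", "BDI_II", "PAQ", "BPQ_A", "BPQ_supra", "BPQ_sub")


def main() -> None:
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    lms = LMSReference.from_tsv(ROOT / "cohort" / "lms_reference_synthetic.tsv")
    meta["bmi_sds"] = [bmi_sds(b, a, s, lms)
                       for b, a, s in zip(meta["bmi"], meta["age"], meta["sex"])]

    per_metric = pd.read_csv(ROOT / "table4_per_metric.tsv", sep="\t")
    flagged = per_metric[per_metric["p_adjusted"] < 0.05]

    frame = meta[list(QUESTIONNAIRES)].copy()
    frame["bmi_sds"] = meta["bmi_sds"]
    from analysis_io import load_metric_column  # local helper below

    for _, row in flagged.iterrows():
        frame[f"{row['region']}_{row['metric']}"] = load_metric_column(
            ROOT / "cohort", row["metric"], row["region"], meta.index)

    screen = correlation_screen(frame, family="primary_screen")
    stacked = pd.concat([screen.tau.stack().rename("tau"),
                         screen.p_raw.stack().rename("p"),
                         screen.p_adjusted.stack().rename("p_adjusted")], axis=1)
    stacked.index.names = ["var1", "var2"]
    out = ROOT / "table5_correlations.tsv"
    stacked.reset_index().to_csv(out, sep="\t", index=False)

    brain_cols = [c for c in frame.columns
                  if c not in QUESTIONNAIRES and c != "bmi_sds"]
    for col in brain_cols:
        sig = screen.p_adjusted[col].drop(col)
        taus = screen.tau[col].drop(col)
        hits = taus[sig < 0.05]
        print(f"{col}: {len(hits)} FDR-significant correlates "
              f"(tau range {taus.min():.2f} to {taus.max():.2f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
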
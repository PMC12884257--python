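#!/usr/bin/env python
"""Backward-elimination regression on precuneus thickness.

Starting from the full theory-driven model (age, BMI-SDS, anxiety total,
body-perception and alexithymia subscales, selected eating-disorder
subscales), predictors are removed while the largest p exceeds
POUT = 0.10; VIFs screen collinearity. Writes results/table6_regression.tsv.
"""

from pathlib import Path

from npcmorph.io import read_metadata
from npcmorph.regression import backward_eliminate

from analysis_io import load_metric_column

ROOT = Path(__file__).resolve().parents[1] / "results"
PREDICTORS = ("age", "bmi_sds", "BAI", "BPQ_A", "BPQ_supra", "BPQ_sub",
              "PAQ_NDIF", "PAQ_PDIF", "PAQ_NDDF", "PAQ_PDDF", "PAQ_EOT",
              "EDI_DT", "EDI_P", "EDI_MF", "EDI_SI", "EDI_ID", "EDI_IN")


def main() -> None:
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    y = load_metric_column(ROOT / "cohort", "thickness", "precuneus", meta.index)
    X = meta[list(PREDICTORS)].astype(float)
    model = backward_eliminate(y, X, p_out=0.10, p_in=0.05)

    table = model.coefficients.copy()
    table.insert(0, "predictor", table.index)
    table["adj_R2"] = model.adj_r_squared
    out = ROOT / "table6_regression.tsv"
    table.to_csv(out, sep="\t", index=False)

    print(table.round(4).to_string(index=False))
    print(f"\nremoved (in order): {[name for name, _ in model.elimination_trace]}")
    print(f"retained: {model.predictors}; adjusted R^2 = {model.adj_r_squared:.3f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
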
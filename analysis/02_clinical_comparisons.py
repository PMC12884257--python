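#!/usr/bin/env python
"""Compare clinical and psychological measures between groups.

For each questionnaire total, age and BMI-SDS: Shapiro-Wilk/Levene-gated
choice among pooled t, Welch t and Mann-Whitney U, with Cohen's d or
r = Z/sqrt(N) as effect size and BH-FDR over the family. Writes
results/table1_clinical.tsv.
"""

from pathlib import Path

import pandas as pd

from npcmorph.group_stats import compare_groups, fdr_bh
from npcmorph.io import read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"
VARIABLES = ("age", "bmi_sds", "EDI_II", "BAI", "BDI_II", "PAQ",
             "BPQ_A", "BPQ_supra", "BPQ_sub")


def main() -> None:
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    is_p = meta["group"] == "patient"
    rows = []
    for var in VARIABLES:
        res = compare_groups(meta.loc[is_p, var].to_numpy(float),
                             meta.loc[~is_p, var].to_numpy(float),
                             variable=var, family="clinical")
        rows.append({"variable": var, "test": res.test_kind,
                     "statistic": round(res.statistic, 3),
                     "p": res.p_raw, "effect_size": round(res.effect_size, 3),
                     "effect_kind": "r" if res.test_kind == "mann_whitney" else "d"})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = fdr_bh(table["p"].to_numpy())
    out = ROOT / "table1_clinical.tsv"
    table.to_csv(out, sep="\t", index=False)

    sig = table[table["p_adjusted"] < 0.05]["variable"].tolist()
    print(table.to_string(index=False))
    print(f"\n{len(sig)}/{len(table)} variables differ after FDR: {sig}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
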
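"""Shared loading helper for the numbered analysis scripts."""

from pathlib import Path

from npcmorph.io import combine_hemispheres, read_stats_table


def load_metric_column(cohort_dir: Path, metric: str, region: str, index):
    """One region's combined-hemisphere values aligned to ``index``."""
    lh = read_stats_table(cohort_dir / f"lh.aparc.{metric}.tsv", metric, "left")
    rh = read_stats_table(cohort_dir / f"rh.aparc.{metric}.tsv", metric, "right")
    return combine_hemispheres(lh, rh).values.loc[index, region]
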
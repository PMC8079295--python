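"""The trial-level hypothesis tests around the threshold estimate.

Baseline side preference (one-sample Wilcoxon vs 50 %), change of a movement
metric across the trial (Friedman), interval-vs-baseline comparisons with
Holm correction, and the repeatability ANOVA.
"""

import numpy as np
import pandas as pd

import shuttlebox as sb

cfg = sb.SimulationConfig(seed=3)
summaries = []
for fish in sb.sample_cohort(cfg):
    log = sb.simulate_trajectory(fish, cfg)
    summaries.extend(sb.bin_intervals(log, cfg.protocol, cfg.geometry))
df = sb.summaries_frame(summaries)

base = df[df.interval_kind == "baseline"].residence_hypoxic
pref = sb.one_sample_wilcoxon(base, 50.0)
print(f"side preference: min occupancy {base.min():.1f} %, "
      f"Wilcoxon W = {pref.statistic:.0f}, p = {pref.p:.2g}")

matrix = df.pivot(index="fish_id", columns="interval_id",
                  values="shelter_time")
fried = sb.friedman_test(matrix)
print(f"shelter time across the trial: Friedman chi2 = {fried.statistic:.1f}, "
      f"p = {fried.p:.2g}")

bins = {iv: df[df.interval_id == iv].sort_values("fish_id")
        .shelter_time.to_numpy()
        for iv in df.interval_id.unique() if iv != "baseline"}
results = sb.pairwise_wilcoxon_holm(
    df[df.interval_kind == "baseline"].sort_values("fish_id")
    .shelter_time.to_numpy(), bins, metric="shelter_time")
sig = [r.name for r in results if r.p_adjusted is not None and r.p_adjusted < 0.05]
print(f"bins deviating from baseline shelter time (Holm-adjusted p<0.05): {sig}")

nominal = df.drop_duplicates("interval_id").set_index("interval_id").nominal_do
print("  (those bins correspond to DO "
      f"{sorted(set(round(nominal[b]) for b in sig))} %sat)")
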
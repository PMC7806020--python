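"""A scaled-down end-to-end study: simulate, measure, summarize, test.

Runs a few trials of each condition (control, open-loop, closed-loop) with
shortened durations, prints the per-condition metric summary (mean +- SEM
per 2-min bin), and the transfer-entropy surrogate tests.  The full-scale
study (16 trials x 16 min) uses the same call with the default config.
"""

import pandas as pd

from robopred import StudyConfig, run_study

pd.set_option("display.width", 200)

config = StudyConfig(
    n_trials_per_condition=4,
    seed=11,
    habituation_s=60,
    observation_s=180,
    n_perm=500,
)
report = run_study(config)

cols = ["condition", "time_bin", "avg_height_cm_mean", "avg_height_cm_sem",
        "pct_time_bottom_third_mean", "pct_time_opposite_half_mean",
        "pct_robot_attacking_mean"]
print(report.summary[cols].round(2).to_string(index=False))

print("\ntransfer-entropy surrogate tests:")
for (condition, axis), r in report.te_tests.items():
    flag = "SIGNIFICANT" if r.significant else "not significant"
    print(f"  {condition:11s} {axis:10s} mean TE {r.observed_mean_te:.4f} bits "
          f"(q95 {r.q95:.4f}) -> {flag}")
print(
    "\nthe default fish model flees attacks vertically in both replica"
    "\nconditions, so at full scale the vertical tests tend to be significant"
    "\nand the horizontal ones do not (no horizontal coupling)."
)
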
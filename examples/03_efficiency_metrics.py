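"""Carbon-use, sequestration and stabilisation efficiencies along a run.

Computes the annual metric table for a 24-year drought scenario: CUE_I
(respiration from labile pools per unit labile stock), CUE_S (same for the
stable pools), their ratio CSE, and the stabilisation efficiency
SE = dHUM/dBIO between consecutive years, each tagged with the soil-water
zone and scenario phase.
"""

import dataclasses

from droughtsoc import RunConfig, annual_metric_table, run_experiment

cfg = RunConfig(seed=1, total_years=48, drought_lengths=(24,))
cfg.synth = dataclasses.replace(cfg.synth, seed=1)
exp = run_experiment(cfg)
run, plan = exp.scenarios["24-year"]

table = annual_metric_table(run, plan, scenario="24-year")
print(table[["year", "phase", "water", "zone", "cue_i", "cue_s", "cse", "se"]]
      .head(8).round(4).to_string(index=False))

by_phase = table.groupby("phase")[["cue_i", "cue_s", "cse"]].mean()
print("\nphase means:")
print(by_phase.round(4).to_string())
ratio = (table["cue_i"] / table["cue_s"]).mean()
print(f"\nCUE_I / CUE_S averages {ratio:.1f}: fresh-input pools turn over much "
      "faster than the stable pools,")
print("and CSE > 1 throughout means labile-derived respiration dominates; "
      "drought-phase CSE above the")
print("PDRS value signals relatively faster labile turnover while the soil "
      "is dry.")
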
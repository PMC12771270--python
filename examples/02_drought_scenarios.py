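"""Simulate 192-year drought-frequency scenarios and summarise pool impacts.

Spins the four-pool model up to a periodic steady state under the control
block, rescales to the site SOC stock, then runs the control series and the
12- and 96-year drought scenarios (8 events vs 1 event over 192 years) and
prints the drought-minus-control pool deltas per phase.
"""

import dataclasses

from droughtsoc import RunConfig, run_experiment
from droughtsoc.pipeline import pool_frame
from droughtsoc.scenario import phase_summaries

cfg = RunConfig(seed=1, drought_lengths=(12, 96))
cfg.synth = dataclasses.replace(cfg.synth, seed=1)
exp = run_experiment(cfg)

print(f"spun-up SOC: {exp.init_state.total_soc:.0f} kg C/ha over "
      f"{len(exp.layers)} layers")
control_frame = pool_frame(exp.control)
for label, (run, plan) in exp.scenarios.items():
    print(f"\n{label} scenario: {plan.n_events} drought event(s), "
          f"PDRS length {plan.drought_length} yr")
    summary = phase_summaries(pool_frame(run), control_frame, plan)
    pooled = summary[summary["event"] == 0].set_index("variable")
    for pool in ("bio", "hum", "soc"):
        row = pooled.loc[pool]
        print(f"  {pool.upper():>4}: max impact {row['max_impact']:>8.1f} kg C/ha, "
              f"drought rate {row['annual_rate_drought']:>6.1f}, "
              f"PDRS rate {row['annual_rate_pdrs']:>6.1f} kg C/ha/yr, "
              f"end-PDRS {row['end_pdrs_pct']:>6.2f}% of control")

# Negative max impacts show drought-driven pool depletion (mean over events);
# the PDRS rate shows recovery speed after rewetting. HUM stays below control
# at the end of recovery in both scenarios - stabilised carbon does not fully
# rebuild within a recovery window equal to the drought length.
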
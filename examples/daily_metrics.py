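"""Compute the per-horse per-24 h outcome table for one group and treatment.

Each 72 h recording gives three 24 h blocks per horse: bout counts and
recumbency durations split by lying surface, the under-30-min flag (the
REM-sleep proxy), and the lateral / members-present / forced-termination
percentages.
"""

from equirest import SimConfig, day_metrics_table, flag_under_72h, simulate_schedule
from equirest.pipeline import treatment_label
from equirest.synth import render_annotations

config = SimConfig(seed=7)
schedule = simulate_schedule(config, group_id=2, treatment_ratio=0.5)
bouts = [b for bs in schedule.bouts.values() for b in bs]

table = day_metrics_table(
    render_annotations(bouts),
    horses=schedule.horses,
    group_size=len(schedule.horses),
    treatment=treatment_label(schedule.treatment_ratio),
    rank_class=schedule.rank_class,
    group_id=schedule.group_id,
)

cols = ["horse_id", "day_index", "n_bouts_total", "duration_min_total",
        "duration_min_litter", "under_30min", "pct_lateral", "pct_forced"]
print(table[cols].round(1).to_string(index=False))
flags = flag_under_72h(table)
print(f"\nhorses below 30 min recumbency over the whole 72 h: "
      f"{int(flags['under_30min_72h'].sum())} of {len(flags)}")
print("(each row is one horse-day; durations in minutes, percentages of the "
      "day's recumbency or bout count)")
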
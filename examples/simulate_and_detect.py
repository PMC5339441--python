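"""Generate one horse's day of behaviour, render the leg-sensor signal and
recover the lying bouts from it.

A leg-worn 1 Hz accelerometer reads about -1 g while the horse stands and
about 0 g while it lies (the leg is horizontal, so gravity drops out of the
measured axis).  The detector thresholds at -0.75 g, smooths with a 31 s
majority vote and keeps lying runs of at least 30 s.
"""

from equirest import SimConfig, detect_bouts, render_trace, simulate_schedule

config = SimConfig(recording_hours=24.0, seed=42)
schedule = simulate_schedule(config, group_id=1, treatment_ratio=1.0)
horse = schedule.horses[0]
true_bouts = schedule.bouts[horse]

trace = render_trace(true_bouts, config, horse_id=horse)
detected = detect_bouts(trace)

print(f"horse {horse} (rank {schedule.rank_class[horse]}), 24 h at 1 Hz "
      f"-> {len(trace)} samples")
print(f"true bouts >=30 s : {sum(b.duration >= 30 for b in true_bouts)}")
print(f"detected bouts    : {len(detected)}")
for b in detected:
    print(f"  lying {b.start:>6d}..{b.end:>6d} s  ({b.duration / 60:.1f} min)")
total = sum(b.duration for b in detected) / 60
print(f"total recumbency  : {total:.1f} min per 24 h "
      f"({'below' if total < 30 else 'at or above'} the 30 min REM-sleep proxy)")
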
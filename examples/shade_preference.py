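"""Quantify daytime shade selection and run the shifted-shade control.

Simulates an 8-h trial (4 h day, 4 h night) in which the school shelters
under the platform for ~70% of the daylight, then measures: hourly
occupancy fractions against the random-movement baseline, the logistic
probability increment p(shade|day) - p(shade|night), and the same fit
against the neighboring trials' (unshaded) platform positions, where a
genuine platform preference must vanish.
"""

from shoal import (
    SimConfig,
    classify_detections,
    control_shift_analysis,
    fit_shade_preference,
    occupancy_fractions,
    random_baseline,
    simulate_school,
)

HOUR = 3600.0
cfg = SimConfig(
    trial_length=8 * HOUR,
    shade_preference_day=0.7,
    day_night_schedule=((0.0, 4 * HOUR),),
    seed=5,
)
detections, truth = simulate_school(cfg)
# this pond's platform sits at square 'a'; in the rotation it is trial #2,
# with neighbors at 'c' (previous) and 'd' (next)
schedule = cfg.schedule(trial_id=2, shade_rotation=("c", "a", "d", "e", "b"))
classified = classify_detections(detections, cfg.pond, schedule)

print(f"random-movement baseline: {random_baseline(cfg.pond):.3f} "
      "(shade area / pond area)")
print("hour  fraction under shade   n")
for _, row in occupancy_fractions(classified).iterrows():
    day = "day" if schedule.is_day(row.window_start) else "night"
    print(f"  {row.hour_of_day:4.0f}h   {row.fraction:.3f} ({day})       {int(row.n)}")

fit = fit_shade_preference(classified)
print(f"\nlogistic fit: p(shade|day)={fit.p_shade_day:.3f} "
      f"p(shade|night)={fit.p_shade_night:.3f}")
print(f"probability increment = {fit.probability_increment:+.3f} "
      f"(Wald p = {fit.p_value:.2g})")

controls = control_shift_analysis(detections, cfg.pond, schedule)
for side, ctrl in controls.items():
    print(f"control ({side} trial's square): increment = "
          f"{ctrl.probability_increment:+.3f}")
print("\nThe actual-square increment is large and significant; the control "
      "increments sit near zero, so the preference tracks the platform, "
      "not a favorite corner of the pond.")
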
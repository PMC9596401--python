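"""Voronoi interaction networks aggregated over 10-minute windows.

Builds per-frame Voronoi neighbor graphs from a mixed trial, aggregates
them into weighted networks per 10-min window, labels windows by the >10%
under-shade rule, and compares the average weighted degree k and Onnela
weighted transitivity C across categories.  Also reproduces the star-
configuration worked example: a hub held against 9 peripherals for a full
window has kappa = 1, each peripheral 1/9.
"""

from shoal import (
    SimConfig,
    aggregate_network,
    build_aggregated_networks,
    classify_detections,
    network_metrics_table,
    simulate_school,
    synchronize_tracks,
    weighted_degree_metrics,
)

# worked example: a persistent star configuration
star = aggregate_network([[(0, j) for j in range(1, 10)]] * 150, n_fish=10)
kappa, k = weighted_degree_metrics(star)
print(f"persistent 10-fish star: hub kappa = {kappa[0]:.3f}, "
      f"peripheral kappa = {kappa[1]:.3f} (= 1/9), network k = {k:.3f}")

HOUR = 3600.0
cfg = SimConfig(
    trial_length=8 * HOUR,
    shade_preference_day=0.5,
    day_night_schedule=((0.0, 4 * HOUR),),
    seed=11,
)
detections, _ = simulate_school(cfg)
classified = classify_detections(detections, cfg.pond, cfg.schedule())
frames = synchronize_tracks(classified, dt=4.0)
networks = build_aggregated_networks(frames, cfg.pond, cfg.schedule(), window=600.0)
table = network_metrics_table(networks)

print(f"\n{len(networks)} ten-minute networks "
      f"({table.category.value_counts().to_dict()})")
print(table.groupby("category")[["k", "C"]].median().round(3))
print("\nRoaming (open_day) schools keep the most, and most evenly shared, "
      "Voronoi neighbors (highest k and C); sheltering fish keep an "
      "intermediate local order; night wanderers interact least stably.")
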
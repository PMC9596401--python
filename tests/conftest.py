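"""Shared fixtures: small seeded simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from shoal import SimConfig, classify_detections, simulate_school

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

HOUR = 3600.0


@pytest.fixture(scope="session")
def preset_runs():
    """30-min day-only runs of the three pure behavioral presets."""
    out = {}
    for state in ("polarized", "swarm", "milling"):
        cfg = SimConfig(
            behavior_state=state,
            trial_length=1800.0,
            day_night_schedule=((0.0, 1800.0),),
            seed=3,
        )
        out[state] = simulate_school(cfg)
    return out


@pytest.fixture(scope="session")
def mixed_run():
    """4-h mixed-schedule trial (2 h day, 2 h night), moderate preference."""
    cfg = SimConfig(
        trial_length=4 * HOUR,
        shade_preference_day=0.6,
        day_night_schedule=((0.0, 2 * HOUR),),
        seed=7,
    )
    detections, truth = simulate_school(cfg)
    schedule = cfg.schedule(trial_id=2, shade_rotation=("c", "a", "d", "e", "b"))
    classified = classify_detections(detections, cfg.pond, schedule)
    return {
        "config": cfg,
        "detections": detections,
        "classified": classified,
        "truth": truth,
        "geometry": cfg.pond,
        "schedule": schedule,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
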
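"""Shade selection: occupancy fractions, baseline, logistic preference model."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from shoal import (
    control_shift_analysis,
    fit_shade_preference,
    occupancy_fractions,
    random_baseline,
)
from shoal.geometry import PondGeometry, TrialSchedule
from shoal.preprocess import classify_detections

HOUR = 3600.0


def _classified(t, under_shade, is_day):
    return pd.DataFrame(
        {
            "fish_id": 0,
            "t": np.asarray(t, float),
            "under_shade": np.asarray(under_shade, bool),
            "is_day": np.asarray(is_day, bool),
        }
    )


class TestOccupancyFractions:
    def test_full_shade_window_is_one(self):
        df = _classified([10.0, 20.0, 30.0], [1, 1, 1], [1, 1, 1])
        out = occupancy_fractions(df)
        assert len(out) == 1 and out.fraction.iloc[0] == 1.0 and out.n.iloc[0] == 3

    def test_empty_windows_omitted(self):
        df = _classified([10.0, 5 * HOUR + 1], [1, 0], [1, 1])
        out = occupancy_fractions(df)
        assert list(out.window_start) == [0.0, 5 * HOUR]

    def test_weighted_mean_equals_global_fraction(self, rng):
        t = rng.uniform(0, 12 * HOUR, 5000)
        shade = rng.random(5000) < 0.3
        df = _classified(t, shade, np.ones(5000))
        out = occupancy_fractions(df)
        assert (out.fraction >= 0).all() and (out.fraction <= 1).all()
        weighted = np.average(out.fraction, weights=out.n)
        assert weighted == pytest.approx(shade.mean(), abs=1e-12)

    def test_uniform_fish_near_area_ratio(self, rng):
        """Spatially uniform positions occupy shade at the area-ratio rate."""
        geom = PondGeometry.default_pond("a")
        sched = TrialSchedule.regular(12 * HOUR, sunrise=0.0, sunset=12 * HOUR)
        n = 40_000
        df = pd.DataFrame(
            {
                "fish_id": 0,
                "t": np.sort(rng.uniform(0, 12 * HOUR, n)),
                "x": rng.uniform(0, 40, n),
                "y": rng.uniform(0, 25, n),
            }
        )
        cl = classify_detections(df, geom, sched)
        frac = occupancy_fractions(cl).fraction.mean()
        assert frac == pytest.approx(random_baseline(geom), abs=0.01)


class TestRandomBaseline:
    def test_area_ratio(self):
        geom = PondGeometry(box(0, 0, 40, 25), {"a": box(0, 0, 5, 5)}, "a")
        assert random_baseline(geom) == pytest.approx(25.0 / 1000.0)

    def test_shade_equal_to_pond_gives_one(self):
        geom = PondGeometry(box(0, 0, 10, 10), {"a": box(0, 0, 10, 10)}, "a")
        assert random_baseline(geom) == pytest.approx(1.0)

    def test_label_position_does_not_matter(self):
        geom = PondGeometry.default_pond("a")
        fractions = {lab: random_baseline(geom, lab) for lab in "abcde"}
        assert len(set(np.round(list(fractions.values()), 12))) == 1


class TestLogisticFit:
    def _bernoulli(self, rng, p_day, p_night, n=10_000):
        day = rng.random(n) < p_day
        night = rng.random(n) < p_night
        return _classified(
            np.arange(2 * n, dtype=float),
            np.concatenate([day, night]),
            np.concatenate([np.ones(n, bool), np.zeros(n, bool)]),
        )

    def test_recovers_generating_probabilities(self, rng):
        fit = fit_shade_preference(self._bernoulli(rng, 0.6, 0.1))
        assert fit.probability_increment == pytest.approx(0.5, abs=0.02)
        assert fit.p_value < 1e-3
        # fitted log-odds within 3 SE of the generating values (n = 10,000)
        se0 = 1.0 / np.sqrt(10_000 * 0.1 * 0.9)
        se1 = np.sqrt(se0**2 + 1.0 / (10_000 * 0.6 * 0.4))
        assert abs(fit.intercept - np.log(0.1 / 0.9)) < 3 * se0
        assert abs(fit.daylight_coef - (np.log(0.6 / 0.4) - np.log(0.1 / 0.9))) < 3 * se1

    def test_no_effect_gives_near_zero_increment(self, rng):
        fit = fit_shade_preference(self._bernoulli(rng, 0.3, 0.3, n=2000))
        assert abs(fit.probability_increment) < 0.05
        assert fit.p_value > 1e-3

    def test_increment_sign_matches_empirical_difference(self, rng):
        for p_day, p_night in [(0.2, 0.5), (0.5, 0.2), (0.45, 0.4)]:
            df = self._bernoulli(rng, p_day, p_night, n=3000)
            fit = fit_shade_preference(df)
            empirical = df[df.is_day].under_shade.mean() - df[~df.is_day].under_shade.mean()
            assert np.sign(fit.probability_increment) == np.sign(empirical)

    def test_complete_separation_flagged(self, rng):
        df = self._bernoulli(rng, 0.7, 0.0, n=500)
        df.loc[~df.is_day, "under_shade"] = False
        with pytest.warns(RuntimeWarning):
            fit = fit_shade_preference(df)
        assert fit.separable
        assert fit.probability_increment == pytest.approx(
            df[df.is_day].under_shade.mean(), abs=1e-12
        )

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            fit_shade_preference(_classified([0.0, 1.0], [1, 1], [1, 0]))
        with pytest.raises(ValueError):
            fit_shade_preference(_classified([0.0, 1.0], [1, 0], [1, 1]))


class TestControlShift:
    def _uniform_detections(self, rng, n=20_000):
        return pd.DataFrame(
            {
                "fish_id": 0,
                "t": np.sort(rng.uniform(0, 24 * HOUR, n)),
                "x": rng.uniform(0, 40, n),
                "y": rng.uniform(0, 25, n),
            }
        )

    def test_uniform_fish_show_no_preference_anywhere(self, rng):
        geom = PondGeometry.default_pond("a")
        sched = TrialSchedule.regular(24 * HOUR, trial_id=2, shade_rotation=("c", "a", "d", "e", "b"))
        det = self._uniform_detections(rng)
        actual = fit_shade_preference(classify_detections(det, geom, sched))
        controls = control_shift_analysis(det, geom, sched)
        assert abs(actual.probability_increment) < 0.02
        for fit in controls.values():
            assert abs(fit.probability_increment) < 0.02

    def test_degenerate_rotation_reproduces_actual_fit(self, rng):
        geom = PondGeometry.default_pond("a")
        sched = TrialSchedule.regular(24 * HOUR, trial_id=2, shade_rotation=("a", "a", "a"))
        det = self._uniform_detections(rng, n=5000)
        actual = fit_shade_preference(classify_detections(det, geom, sched))
        controls = control_shift_analysis(det, geom, sched)
        for fit in controls.values():
            assert fit.probability_increment == pytest.approx(
                actual.probability_increment, abs=1e-12
            )

    def test_trial_without_neighbors_raises(self, rng):
        geom = PondGeometry.default_pond("a")
        sched = TrialSchedule.regular(24 * HOUR, trial_id=1, shade_rotation=("a",))
        with pytest.raises(ValueError):
            control_shift_analysis(self._uniform_detections(rng, 2000), geom, sched)
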
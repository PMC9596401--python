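"""Speed time series: segmentation, distributional summaries, permutation tests.

Speeds are computed on raw detections (distance over time between
consecutive fixes), before any resampling.  Trajectories are split at every
category change (shade_day / open_day / night) and at every break in
consecutiveness — an inter-detection interval longer than 10 s, the
telemetry system's stated upper tail.  Only segments with more than 50
consecutive observations are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeedSegment",
    "SpeedSummary",
    "extract_speed_segments",
    "speed_summary",
    "complementary_cdf",
    "permutation_test",
]

logger = logging.getLogger(__name__)

#: detections further apart than this (s) are not "consecutive"
MAX_CONSECUTIVE_GAP = 10.0


@dataclass(frozen=True)
class SpeedSegment:
    """A contiguous, single-category speed series of one fish."""

    fish_id: object
    category: str
    t: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.v.size


@dataclass(frozen=True)
class SpeedSummary:
    """Distributional summary of pooled speeds for one category."""

    category: str
    n: int
    mean: float
    sem: float
    skewness: float
    skewness_se: float
    ccdf_v: np.ndarray = field(repr=False)
    ccdf_p: np.ndarray = field(repr=False)


def extract_speed_segments(
    classified: pd.DataFrame,
    min_len: int = 50,
    max_gap: float = MAX_CONSECUTIVE_GAP,
) -> list[SpeedSegment]:
    """Category-labelled speed segments from classified detections.

    Trajectories are split per fish at category changes and at
    inter-detection gaps > ``max_gap``; within each run of more than
    ``min_len`` consecutive observations, ``v_i = |pos_{i+1} - pos_i| /
    (t_{i+1} - t_i)`` (timestamped at the interval midpoint).
    """
    if "category" not in classified.columns:
        raise ValueError("detections must carry a category column")
    segments: list[SpeedSegment] = []
    for fish_id, traj in classified.groupby("fish_id", sort=True):
        t = traj["t"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotonic timestamps for fish {fish_id!r}")
        x = traj["x"].to_numpy(float)
        y = traj["y"].to_numpy(float)
        cat = traj["category"].to_numpy()
        breaks = np.flatnonzero((np.diff(t) > max_gap) | (cat[1:] != cat[:-1])) + 1
        for idx in np.split(np.arange(t.size), breaks):
            if idx.size <= min_len:
                continue
            ti, xi, yi = t[idx], x[idx], y[idx]
            dt = np.diff(ti)
            v = np.hypot(np.diff(xi), np.diff(yi)) / dt
            segments.append(
                SpeedSegment(
                    fish_id=fish_id,
                    category=str(cat[idx[0]]),
                    t=(ti[:-1] + ti[1:]) / 2.0,
                    v=v,
                )
            )
    return segments


def complementary_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical P(V > v) on the sorted unique values, prepended with v=0.

    The returned probability is 1 at v = 0 (speeds are non-negative) and
    decreases to 0 at the sample maximum.
    """
    v = np.sort(np.asarray(values, dtype=float))
    uniq, counts = np.unique(v, return_counts=True)
    exceed = v.size - np.cumsum(counts)
    p = exceed / v.size
    if uniq.size == 0 or uniq[0] > 0:
        uniq = np.concatenate([[0.0], uniq])
        p = np.concatenate([[1.0], p])
    return uniq, p


def _bootstrap_skew_se(v: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(np.std(stats.skew(v[idx], axis=1), ddof=1))


def speed_summary(
    segments: list[SpeedSegment],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> dict[str, SpeedSummary]:
    """Pooled per-category mean +/- SEM, skewness +/- bootstrap SE, and CCDF.

    Skewness is the Fisher (moment) coefficient; its standard error comes
    from a seeded nonparametric bootstrap over the pooled speed values.
    Categories with fewer than two values are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    pooled: dict[str, list[np.ndarray]] = {}
    for seg in segments:
        pooled.setdefault(seg.category, []).append(seg.v)
    out: dict[str, SpeedSummary] = {}
    for category in sorted(pooled):
        v = np.concatenate(pooled[category])
        if v.size < 2:
            warnings.warn(f"category {category!r} has <2 speeds; omitted", stacklevel=2)
            continue
        sd = v.std(ddof=1)
        if np.ptp(v) == 0.0:
            raise ValueError(
                f"category {category!r} has constant speeds; skewness undefined"
            )
        ccdf_v, ccdf_p = complementary_cdf(v)
        out[category] = SpeedSummary(
            category=category,
            n=int(v.size),
            mean=float(v.mean()),
            sem=float(sd / np.sqrt(v.size)),
            skewness=float(stats.skew(v)),
            skewness_se=_bootstrap_skew_se(v, n_boot, rng),
            ccdf_v=ccdf_v,
            ccdf_p=ccdf_p,
        )
    return out


def _statistic(a: np.ndarray, b: np.ndarray, kind: str, axis: int = -1) -> np.ndarray:
    if kind == "mean_diff":
        return np.mean(a, axis=axis) - np.mean(b, axis=axis)
    if kind == "skewness_diff":
        return stats.skew(a, axis=axis) - stats.skew(b, axis=axis)
    raise ValueError(f"unknown statistic {kind!r}")


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    statistic: str = "mean_diff",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for a difference statistic.

    Labels are randomly reassigned ``n_perm`` times; the add-one estimate
    ``p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1)`` avoids p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    t_obs = abs(float(_statistic(a, b, statistic)))
    if t_obs == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    # canonical pool (sorted, larger group size first) so that swapping the
    # two group labels yields the identical p-value for the same seed
    if b.size > a.size:
        a, b = b, a
    pool = np.sort(np.concatenate([a, b]))
    n_a = a.size
    count = 0
    # permute in blocks to bound memory at large n
    block = max(1, int(2_000_000 // max(pool.size, 1)))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        perm = rng.permuted(np.broadcast_to(pool, (k, pool.size)).copy(), axis=1)
        t_perm = np.abs(_statistic(perm[:, :n_a], perm[:, n_a:], statistic))
        count += int(np.sum(t_perm >= t_obs))
        done += k
    return (1 + count) / (n_perm + 1)
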
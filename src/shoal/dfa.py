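"""Detrended fluctuation analysis (DFA) for speed time series.

DFA estimates the Hurst exponent ``h`` of a (possibly non-stationary) series
``v(t)`` of length ``m``:

1. integrate the mean-centered series into the profile
   ``Y(t) = sum_{i<=t} (v(i) - <v>)``;
2. cut the profile into ``m_n = floor(m / n)`` non-overlapping blocks of
   size ``n``, fit an ordinary-least-squares line in each block and subtract
   it, giving the detrended profile ``Y_n(t)``;
3. compute the root-mean-square fluctuation
   ``F(n) = sqrt(mean of Y_n(t)^2 over all retained points)``;
4. fit ``log F(n) ~ h log n`` by OLS over a log-spaced grid of scales.

``h ~ 0.5`` indicates an uncorrelated (or short-range correlated) series,
``h > 0.5`` long-range persistence, ``h < 0.5`` anti-persistence.  Order-1
(linear) detrending is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DFAResult",
    "dfa_profile",
    "fluctuation_function",
    "default_scales",
    "estimate_hurst",
    "shuffle_control",
]

#: shortest series accepted by :func:`estimate_hurst`; below this there are
#: too few usable scales for a stable log-log fit
MIN_SERIES_LENGTH = 128


@dataclass(frozen=True)
class DFAResult:
    """Outcome of a DFA fit on one series."""

    hurst: float
    intercept: float
    r_squared: float
    scales: np.ndarray = field(repr=False)
    fluctuations: np.ndarray = field(repr=False)
    length: int = 0

    @property
    def partitions(self) -> np.ndarray:
        """Number of non-overlapping blocks ``m_n = floor(m / n)`` per scale."""
        return self.length // self.scales


def dfa_profile(v: np.ndarray) -> np.ndarray:
    """Integrated profile Y(t) of the mean-centered series.

    The profile telescopes back to ~0 at the last sample.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("input must be a 1-D series with at least 2 samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("input contains non-finite values")
    return np.cumsum(v - v.mean())


def fluctuation_function(profile: np.ndarray, scale: int) -> float:
    """Root-mean-square fluctuation F(n) of a profile at one scale.

    The profile is cut into ``floor(m / n)`` forward non-overlapping blocks
    of size ``n`` (any trailing remainder is dropped), each block is
    linearly detrended by OLS, and F(n) is the square root of the mean
    squared residual over all retained points.
    """
    y = np.asarray(profile, dtype=float)
    m = y.size
    scale = int(scale)
    if scale < 4:
        raise ValueError("scale must be >= 4")
    n_blocks = m // scale
    if n_blocks < 2:
        raise ValueError(f"scale {scale} leaves fewer than 2 blocks for length {m}")
    blocks = y[: n_blocks * scale].reshape(n_blocks, scale)
    t = np.arange(scale, dtype=float)
    # OLS residuals of each block against (1, t); the projector depends only
    # on the block size, so all blocks are detrended in one shot.
    x = np.column_stack([np.ones(scale), t])
    beta, *_ = np.linalg.lstsq(x, blocks.T, rcond=None)
    resid = blocks.T - x @ beta
    return float(np.sqrt(np.mean(resid**2)))


def default_scales(length: int, n_scales: int = 20, min_scale: int = 10) -> np.ndarray:
    """Log-spaced integer scale grid in [min_scale, length // 4], deduplicated."""
    max_scale = length // 4
    if max_scale < min_scale:
        raise ValueError(f"series of length {length} too short for DFA scale grid")
    grid = np.unique(
        np.round(np.geomspace(min_scale, max_scale, n_scales)).astype(int)
    )
    return grid


def estimate_hurst(
    v: np.ndarray,
    scales: np.ndarray | None = None,
    n_scales: int = 20,
    min_scale: int = 10,
) -> DFAResult:
    """Estimate the Hurst exponent of a series by DFA.

    Parameters
    ----------
    v : series of length >= 128.
    scales : explicit strictly increasing integer scales; if omitted, ~20
        log-spaced scales in [10, len(v) // 4].
    """
    v = np.asarray(v, dtype=float)
    m = v.size
    if m < MIN_SERIES_LENGTH:
        raise ValueError(f"series of length {m} is shorter than {MIN_SERIES_LENGTH}")
    if scales is None:
        scales = default_scales(m, n_scales=n_scales, min_scale=min_scale)
    else:
        scales = np.asarray(scales, dtype=int)
        if scales.ndim != 1 or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing")
    profile = dfa_profile(v)
    fluct = np.array([fluctuation_function(profile, n) for n in scales])
    usable = fluct > 0.0
    if usable.sum() < 4:
        raise ValueError("fewer than 4 scales with positive fluctuation")
    logn = np.log(scales[usable])
    logf = np.log(fluct[usable])
    slope, intercept = np.polyfit(logn, logf, 1)
    fitted = slope * logn + intercept
    ss_res = np.sum((logf - fitted) ** 2)
    ss_tot = np.sum((logf - logf.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(
        hurst=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        scales=scales[usable],
        fluctuations=fluct[usable],
        length=m,
    )


def shuffle_control(
    v: np.ndarray,
    n_shuffles: int,
    seed: int | np.random.Generator | None = None,
    **dfa_kwargs,
) -> np.ndarray:
    """Hurst estimates on random permutations of the series.

    Shuffling destroys temporal ordering, so a series whose persistence is
    genuine yields shuffled estimates near 0.5.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = estimate_hurst(rng.permutation(v), **dfa_kwargs).hurst
    return out
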
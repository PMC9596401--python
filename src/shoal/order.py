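"""School order parameters on synchronized 4-s frames.

With ``u_i`` the unit direction vector of fish ``i`` (forward displacement
between consecutive grid frames) and ``r_i`` the unit vector from the school
center of mass to fish ``i``, the per-frame observables are

    polarization  O_p = |sum_i u_i| / N          in [0, 1]
    rotation      O_r = |sum_i (u_i x r_i)_z| / N  in [0, 1]

O_p ~ 1 is an aligned (polarized) school, O_p ~ 0 a disordered swarm;
O_r ~ 1 is coherent milling around the center of mass.  Frames with fewer
than five usable fish are skipped; fish with zero displacement, an invalid
grid position, or sitting exactly at the center of mass are excluded from
the frame.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .geometry import PondGeometry, TrialSchedule
from .preprocess import FrameSet

__all__ = [
    "direction_vectors",
    "polarization",
    "rotation",
    "compute_order_frames",
    "order_distributions",
]

logger = logging.getLogger(__name__)

MIN_FISH_PER_FRAME = 5


def direction_vectors(frames: FrameSet) -> tuple[np.ndarray, np.ndarray]:
    """Unit forward-displacement directions on the synchronized grid.

    Returns ``(u, ok)`` with ``u`` of shape (n_frames - 1, n_fish, 2) and
    ``ok`` marking fish valid at both endpoints with non-zero displacement.
    Invalid entries are NaN.
    """
    if frames.n_frames < 2:
        raise ValueError("need at least two frames to form directions")
    disp = frames.xy[1:] - frames.xy[:-1]
    norm = np.linalg.norm(disp, axis=-1)
    ok = frames.valid[1:] & frames.valid[:-1] & (norm > 0)
    u = np.full_like(disp, np.nan)
    u[ok] = disp[ok] / norm[ok, None]
    return u, ok


def polarization(u: np.ndarray) -> float:
    """O_p = |sum u_i| / N for one frame of unit direction vectors."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != 2 or u.shape[0] == 0:
        raise ValueError("u must have shape (N, 2) with N >= 1")
    return float(np.linalg.norm(u.sum(axis=0)) / u.shape[0])


def rotation(u: np.ndarray, positions: np.ndarray) -> float:
    """O_r = |sum (u_i x r_i)_z| / N about the school center of mass.

    The 2-D cross product is its scalar z-component.  Fish sitting exactly
    at the center of mass (r undefined) are excluded from the frame.
    """
    u = np.asarray(u, dtype=float)
    p = np.asarray(positions, dtype=float)
    if u.shape != p.shape or u.ndim != 2 or u.shape[1] != 2 or u.shape[0] == 0:
        raise ValueError("u and positions must both have shape (N, 2), N >= 1")
    com = p.mean(axis=0)
    r = p - com
    norms = np.linalg.norm(r, axis=1)
    keep = norms > 1e-12 * max(1.0, float(norms.max()))
    if not np.any(keep):
        raise ValueError("all fish coincide with the center of mass")
    r = r[keep] / norms[keep, None]
    uu = u[keep]
    cross_z = uu[:, 0] * r[:, 1] - uu[:, 1] * r[:, 0]
    return float(abs(cross_z.sum()) / keep.sum())


def compute_order_frames(
    frames: FrameSet,
    geometry: PondGeometry | None = None,
    schedule: TrialSchedule | None = None,
    min_fish: int = MIN_FISH_PER_FRAME,
) -> pd.DataFrame:
    """Per-frame O_p and O_r with an optional category label.

    A frame is labelled ``night`` by the clock; otherwise ``shade_day`` when
    at least half of the included fish are under the shade square, else
    ``open_day``.  Without geometry/schedule the category is ``all``.
    Frames with fewer than ``min_fish`` usable fish are skipped (counted in
    the log).
    """
    u, ok = direction_vectors(frames)
    times = frames.times[:-1]
    records = []
    skipped = 0
    for i in range(u.shape[0]):
        mask = ok[i]
        n = int(mask.sum())
        if n < min_fish:
            skipped += 1
            continue
        pos = frames.xy[i][mask]
        o_p = polarization(u[i][mask])
        o_r = rotation(u[i][mask], pos)
        assert 0.0 <= o_p <= 1.0 + 1e-12 and 0.0 <= o_r <= 1.0 + 1e-12
        if geometry is None or schedule is None:
            category = "all"
        elif not schedule.is_day(times[i]):
            category = "night"
        else:
            frac_shade = float(np.mean(geometry.under_shade(pos[:, 0], pos[:, 1])))
            category = "shade_day" if frac_shade >= 0.5 else "open_day"
        records.append(
            {"time": times[i], "n": n, "o_p": o_p, "o_r": o_r, "category": category}
        )
    if skipped:
        logger.info("skipped %d frames with fewer than %d usable fish", skipped, min_fish)
    return pd.DataFrame.from_records(
        records, columns=["time", "n", "o_p", "o_r", "category"]
    )


def order_distributions(
    order_frames: pd.DataFrame,
    grid_size: int = 50,
    min_frames: int = 100,
) -> dict[str, dict]:
    """Joint and marginal summaries of (O_r, O_p) per category.

    For each category: frame count, means, tail probabilities
    P(O_p > 0.9) / P(O_r > 0.9), a ``grid_size``-squared joint histogram
    density on [0, 1]^2, and Gaussian-KDE marginals (Scott bandwidth)
    evaluated on the grid.  Empty categories are omitted.
    """
    edges = np.linspace(0.0, 1.0, grid_size + 1)
    grid = (edges[:-1] + edges[1:]) / 2.0
    out: dict[str, dict] = {}
    for category, sub in order_frames.groupby("category"):
        op = sub["o_p"].to_numpy(float)
        orr = sub["o_r"].to_numpy(float)
        if op.size < min_frames:
            logger.warning(
                "category %s has only %d frames (< %d)", category, op.size, min_frames
            )
        joint, _, _ = np.histogram2d(orr, op, bins=[edges, edges], density=True)
        summary = {
            "n_frames": int(op.size),
            "mean_o_p": float(op.mean()),
            "mean_o_r": float(orr.mean()),
            "p_o_p_gt_0.9": float(np.mean(op > 0.9)),
            "p_o_r_gt_0.9": float(np.mean(orr > 0.9)),
            "joint_density": joint,
            "grid": grid,
        }
        for name, vals in (("o_p", op), ("o_r", orr)):
            if np.std(vals) > 0 and vals.size > 2:
                summary[f"kde_{name}"] = gaussian_kde(vals)(grid)
            else:
                summary[f"kde_{name}"] = None
        out[str(category)] = summary
    return out
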
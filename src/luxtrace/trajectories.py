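"""Per-cell emission trajectories: smoothing, onset times, dark/bright calls.

A trajectory is one cell's emission rate versus time, sampled at the frame
cadence. Trajectories are smoothed with a Gaussian temporal filter
(sigma = 10 minutes by default). The onset time t_half of a responding cell
is the time at which its (smoothed) emission is halfway between its initial
value and its final value; cells whose net response does not exceed three
times the detection floor are classified flat and get no onset time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "OnsetResult",
    "smooth_series",
    "smooth_trajectory",
    "build_trajectories",
    "onset_time",
    "classify_dark",
]


@dataclass
class Trajectory:
    cell_id: int
    times: np.ndarray      # minutes, strictly increasing
    raw: np.ndarray        # photons/minute
    smoothed: np.ndarray   # photons/minute
    filter_sd: float       # minutes

    def value_at(self, t: float, smoothed: bool = True) -> float:
        idx = int(np.argmin(np.abs(self.times - t)))
        return float((self.smoothed if smoothed else self.raw)[idx])


@dataclass
class OnsetResult:
    cell_id: int
    t_half: float | None
    i_initial: float
    i_final: float
    direction: str          # "rising" | "falling" | "flat"


def smooth_series(times, values, filter_sd: float = 10.0) -> np.ndarray:
    """Gaussian-filter a (possibly irregularly sampled) series.

    The kernel is evaluated at the actual sample-time offsets, truncated at
    +/- 3 sigma and renormalized per point, which handles uneven sampling
    and boundaries; a constant series is returned unchanged.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if filter_sd <= 0:
        return v.copy()
    dt = t[:, None] - t[None, :]
    w = np.exp(-(dt**2) / (2.0 * filter_sd**2))
    w[np.abs(dt) > 3.0 * filter_sd] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    return w @ v


def smooth_trajectory(traj: Trajectory, filter_sd: float | None = None) -> Trajectory:
    """Return the trajectory with its smoothed series (re)computed."""
    sd = traj.filter_sd if filter_sd is None else filter_sd
    return Trajectory(
        cell_id=traj.cell_id, times=traj.times, raw=traj.raw,
        smoothed=smooth_series(traj.times, traj.raw, sd), filter_sd=sd,
    )


def build_trajectories(measurements: pd.DataFrame, filter_sd: float = 10.0) -> list[Trajectory]:
    """Assemble trajectories from a photometry measurement table.

    Expects columns ``cell_id``, ``t_start_min``, ``rate_photons_per_min``;
    rows flagged ``excluded`` (if the column exists) are dropped.
    """
    df = measurements
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    out = []
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("t_start_min")
        t = grp["t_start_min"].to_numpy(dtype=float)
        r = grp["rate_photons_per_min"].to_numpy(dtype=float)
        if len(t) < 3:
            continue
        out.append(Trajectory(
            cell_id=int(cid), times=t, raw=r,
            smoothed=smooth_series(t, r, filter_sd), filter_sd=filter_sd,
        ))
    return out


def onset_time(
    traj: Trajectory,
    final_window: float = 10.0,
    noise_floor: float = 0.0,
) -> OnsetResult:
    """Onset time: first crossing of the half-way level of the response.

    ``i_initial`` is the smoothed value at the first frame; ``i_final`` the
    mean of smoothed values within ``final_window`` minutes of the last
    frame (default 10, i.e. the last two frames at the usual cadence --
    wide enough to average down single-frame noise, short enough that the
    final level of a still-rising cell is not underestimated). The onset is the earliest time at which the smoothed series
    crosses (i_initial + i_final)/2, linearly interpolated between frames.
    If the net change does not exceed 3 x ``noise_floor`` the trajectory is
    flat and no onset is defined. Falling trajectories (transient decrease)
    get a defined onset by the same midpoint rule.
    """
    t, s = traj.times, traj.smoothed
    if t[-1] - t[0] < 150.0:
        raise ValueError("trajectory must span at least 150 minutes for an onset time")
    i_init = float(s[0])
    tail = s[t >= t[-1] - final_window]
    i_final = float(tail.mean())
    if abs(i_final - i_init) <= 3.0 * noise_floor:
        return OnsetResult(traj.cell_id, None, i_init, i_final, "flat")
    direction = "rising" if i_final > i_init else "falling"
    mid = 0.5 * (i_init + i_final)
    sign = 1.0 if direction == "rising" else -1.0
    g = sign * (s - mid)           # crosses zero from below at the onset
    t_half = float(t[-1])
    if g[0] >= 0:
        t_half = float(t[0])
    else:
        for k in range(1, len(t)):
            if g[k] >= 0:
                frac = -g[k - 1] / (g[k] - g[k - 1])
                t_half = float(t[k - 1] + frac * (t[k] - t[k - 1]))
                break
    return OnsetResult(traj.cell_id, t_half, i_init, i_final, direction)


def classify_dark(traj: Trajectory, threshold: float = 15.0, at_time: float = 240.0) -> str:
    """Dark/bright call: smoothed level at the frame nearest ``at_time``.

    A cell emitting at or below the detection threshold (default 15
    photons/min) is "dark" -- consistent with no resolvable emission.
    """
    if not (traj.times[0] <= at_time <= traj.times[-1]):
        raise ValueError("at_time outside the trajectory span")
    return "dark" if traj.value_at(at_time) <= threshold else "bright"
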
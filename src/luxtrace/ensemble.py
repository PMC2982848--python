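"""Population-level statistics of single-cell luminescence.

Brightness histograms and percentile bands over time, coefficient of
variation, cooperative-binding (Hill) dose-response fits, median-normalized
distributions, and the sigma_d(tau) temporal-divergence analysis that
quantifies how quickly cells' brightness ranks diverge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import HillParams
from .trajectories import Trajectory

__all__ = [
    "DoseResponsePoint",
    "HillFitResult",
    "BrightnessDistribution",
    "DivergenceCurve",
    "per_cell_level",
    "brightness_distribution",
    "coefficient_of_variation",
    "fit_hill",
    "autocorrelation_divergence",
    "normalized_histogram",
]


@dataclass
class DoseResponsePoint:
    """Per-cell steady levels of one ensemble held at a fixed AI level."""

    ai: float                        # nM
    per_cell_levels: np.ndarray      # photons/min, one entry per cell

    def __post_init__(self) -> None:
        self.per_cell_levels = np.asarray(self.per_cell_levels, dtype=float)
        if self.per_cell_levels.size < 1:
            raise ValueError("need at least one cell per dose-response point")

    @property
    def mean_level(self) -> float:
        return float(self.per_cell_levels.mean())

    @property
    def n_cells(self) -> int:
        return int(self.per_cell_levels.size)


@dataclass
class HillFitResult:
    params: HillParams
    stderr: dict                     # parameter name -> standard error
    rms_resid: float
    converged: bool
    flags: list = field(default_factory=list)


@dataclass
class BrightnessDistribution:
    t: float
    bin_edges: np.ndarray
    counts: np.ndarray
    median: float
    q25: float
    q75: float


@dataclass
class DivergenceCurve:
    taus: np.ndarray                 # minutes
    sigma_d: np.ndarray              # photons/min
    slopes: np.ndarray
    intercepts: np.ndarray
    n_pairs: np.ndarray


def per_cell_level(traj: Trajectory, t_min: float = 100.0, t_max: float = 250.0) -> float:
    """Time-averaged smoothed emission over t in (t_min, t_max] minutes.

    This is the steady per-cell level used for dose-response points and for
    the coefficient of variation (emission recorded after the ensemble has
    responded, t > 100 min).
    """
    sel = (traj.times > t_min) & (traj.times <= t_max)
    if not np.any(sel):
        raise ValueError("trajectory has no samples in the averaging window")
    return float(traj.smoothed[sel].mean())


def brightness_distribution(
    trajectories: list[Trajectory],
    t: float,
    bin_edges,
) -> BrightnessDistribution:
    """Histogram and quartiles of smoothed cell brightness at time ``t``.

    Quartiles use linear interpolation between order statistics.
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    levels = np.array([tr.value_at(t) for tr in trajectories])
    counts, edges = np.histogram(levels, bins=np.asarray(bin_edges, dtype=float))
    q25, med, q75 = np.quantile(levels, [0.25, 0.5, 0.75])
    return BrightnessDistribution(
        t=t, bin_edges=edges, counts=counts,
        median=float(med), q25=float(q25), q75=float(q75),
    )


def coefficient_of_variation(per_cell_levels) -> float:
    """cv = sample standard deviation (n-1 denominator) / mean."""
    x = np.asarray(per_cell_levels, dtype=float)
    if x.size < 2:
        raise ValueError("cv needs at least 2 cells")
    m = x.mean()
    if m <= 0:
        raise ValueError("cv undefined for non-positive mean")
    return float(x.std(ddof=1) / m)


def _hill(ai, i_base, i_max, k_eq, n):
    ai = np.atleast_1d(np.asarray(ai, dtype=float))
    occ = np.zeros_like(ai)
    pos = ai > 0
    with np.errstate(over="ignore"):
        occ[pos] = 1.0 / (1.0 + (k_eq / ai[pos]) ** n)
    return i_base + (i_max - i_base) * occ


def fit_hill(
    points: list[DoseResponsePoint],
    weights: str | None = None,
) -> HillFitResult:
    """Nonlinear least-squares cooperative-binding fit to per-level means.

    Model: I(ai) = i_base + (i_max - i_base) ai^n / (k_eq^n + ai^n).
    Initialization: i_base = min level, i_max = max level, k_eq = the ai
    whose level is nearest half-range, n = 2. Standard errors come from the
    local curvature (covariance) of the least-squares objective.
    ``weights="n_cells"`` weights each level by its cell count.

    The result is flagged (not raised) when the fit cannot be trusted: no
    half-maximum bracketing, non-convergence, or k_eq more than 10x outside
    the sampled ai range.
    """
    ais = np.array([p.ai for p in points], dtype=float)
    ys = np.array([p.mean_level for p in points], dtype=float)
    if len(np.unique(ais)) < 4:
        raise ValueError("need >= 4 distinct AI levels")
    order = np.argsort(ais)
    ais, ys = ais[order], ys[order]
    ns = np.array([points[i].n_cells for i in order], dtype=float)

    flags: list[str] = []
    span = ys.max() - ys.min()
    if span <= 0 or not (ys.min() < 0.5 * (ys.min() + ys.max()) < ys.max()):
        flags.append("no_half_maximum_bracketing")
    half = 0.5 * (ys.min() + ys.max())
    k0 = float(ais[np.argmin(np.abs(ys - half))])
    k0 = k0 if k0 > 0 else float(np.median(ais[ais > 0])) if np.any(ais > 0) else 1.0
    p0 = (float(ys.min()), float(ys.max()), k0, 2.0)
    sigma = 1.0 / np.sqrt(ns) if weights == "n_cells" else None

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # the half-maximal concentration is only identifiable inside
            # (roughly) the sampled range, and cooperativity beyond ~15 is
            # indistinguishable from a step at this sampling; bounding both
            # keeps noisy fits from running away
            max_ai = float(pos_max) if (pos_max := ais.max()) > 0 else 1.0
            popt, pcov = curve_fit(
                _hill, ais, ys, p0=p0, sigma=sigma,
                bounds=([0.0, 0.0, 1e-12, 1e-6], [np.inf, np.inf, 20.0 * max_ai, 15.0]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000,
            )
        converged = True
    except (RuntimeError, ValueError):
        popt = np.array(p0)
        pcov = np.full((4, 4), np.nan)
        converged = False
        flags.append("non_convergence")

    i_base, i_max, k_eq, n = (float(v) for v in popt)
    if i_max < i_base:   # degenerate flat fits can invert the plateau order
        i_base, i_max = i_max, i_base
        flags.append("inverted_plateaus")
    pos = ais[ais > 0]
    if pos.size and (k_eq > 10 * pos.max() or k_eq < pos.min() / 10):
        flags.append("k_eq_outside_sampled_range")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    resid = ys - _hill(ais, *popt)
    return HillFitResult(
        params=HillParams(k_eq=max(k_eq, 1e-12), hill_n=max(n, 1e-6),
                          i_max=i_max, i_base=max(i_base, 0.0)),
        stderr={"i_base": float(perr[0]), "i_max": float(perr[1]),
                "k_eq": float(perr[2]), "hill_n": float(perr[3])},
        rms_resid=float(np.sqrt(np.mean(resid**2))),
        converged=converged, flags=flags,
    )


def autocorrelation_divergence(
    trajectories: list[Trajectory],
    taus,
    t_min: float = 100.0,
    use_smoothed: bool = True,
    per_cell: bool = False,
) -> DivergenceCurve:
    """Temporal divergence sigma_d(tau) of cell brightness.

    For each lag tau, pairs (I(t), I(t + tau)) are pooled over all cells and
    all frames with t >= t_min; an ordinary least-squares line is drawn
    through the pooled scatter, and sigma_d is the sample sd of the vertical
    distances d from that line. Lags with fewer than 10 pairs are omitted
    with a warning. ``per_cell=True`` instead averages sigma_d computed cell
    by cell.
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    t0 = trajectories[0].times
    for tr in trajectories[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
            raise ValueError("trajectories must share a common frame grid")
    dt = float(np.median(np.diff(t0)))
    taus = np.asarray(taus, dtype=float)
    out_taus, out_sd, out_a, out_b, out_n = [], [], [], [], []
    for tau in taus:
        k = int(round(tau / dt))
        if not np.isclose(k * dt, tau) or k <= 0 or k >= len(t0):
            warnings.warn(f"tau={tau} is not a usable multiple of the frame interval; omitted")
            continue
        xs, ys_ = [], []
        for tr in trajectories:
            series = tr.smoothed if use_smoothed else tr.raw
            valid = np.nonzero(t0 >= t_min)[0]
            valid = valid[valid + k < len(t0)]
            xs.append(series[valid])
            ys_.append(series[valid + k])
        x = np.concatenate(xs)
        y = np.concatenate(ys_)
        if x.size < 10:
            warnings.warn(f"tau={tau}: fewer than 10 pairs; omitted")
            continue
        if per_cell:
            sds = []
            for xi, yi in zip(xs, ys_):
                if xi.size >= 3 and np.ptp(xi) > 0:
                    b, a = np.polyfit(xi, yi, 1)
                    sds.append(np.std(yi - (a + b * xi), ddof=1))
            sd = float(np.mean(sds)) if sds else 0.0
            b, a = np.polyfit(x, y, 1) if np.ptp(x) > 0 else (0.0, float(y.mean()))
        else:
            if np.ptp(x) > 0:
                b, a = np.polyfit(x, y, 1)
            else:
                b, a = 0.0, float(y.mean())
            d = y - (a + b * x)
            sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        out_taus.append(tau); out_sd.append(sd)
        out_a.append(float(b)); out_b.append(float(a)); out_n.append(x.size)
    return DivergenceCurve(
        taus=np.array(out_taus), sigma_d=np.array(out_sd),
        slopes=np.array(out_a), intercepts=np.array(out_b),
        n_pairs=np.array(out_n, dtype=int),
    )


def normalized_histogram(levels, bin_edges=None):
    """Median-normalized brightness distribution with its cv.

    Returns ``(normalized_levels, (counts, edges), cv)``; the normalized
    median is exactly 1 and the histogram is invariant under rescaling all
    levels by a positive constant.
    """
    x = np.asarray(levels, dtype=float)
    med = float(np.median(x))
    if med <= 0:
        raise ValueError("median must be > 0 to normalize")
    norm = x / med
    if bin_edges is None:
        bin_edges = np.linspace(0.0, max(5.0, float(norm.max()) + 0.5, 1.0), 26)
    counts, edges = np.histogram(norm, bins=bin_edges)
    return norm, (counts, edges), coefficient_of_variation(x)
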
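"""Synthetic single-cell bioluminescence ensembles and rendered image stacks.

This module generates ground-truthed data with the statistical structure of
low-light microscopy of quorum-sensing bacteria: rod-shaped cells imaged at
0.278 um/pixel, long (ten-minute) photon-counting exposures detecting tens of
photons per minute per cell, Gaussian detector background, log-normally
heterogeneous per-cell induction amplitudes, broadly distributed response
onset times, and multiplicative Ornstein-Uhlenbeck brightness fluctuations.
The ensemble-mean steady response versus autoinducer (AI) concentration
follows a cooperative-binding (Hill) curve.

Every random draw derives from one master seed through stable substream
indexing, so scenes, trajectories and frames are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage
from scipy.special import expit

__all__ = [
    "HillParams",
    "CellPhenotype",
    "EnsembleModel",
    "ImagingModel",
    "CellGeometry",
    "SyntheticScene",
    "substream",
    "bulk_response",
    "draw_ensemble",
    "simulate_trajectories",
    "make_scene",
    "render_frame_pair",
    "render_stack",
    "stable_source_fixture",
]


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent random generator for substream ``key`` of a master seed.

    Uses ``np.random.SeedSequence`` spawn keys, so the mapping
    (master seed, key) -> stream is stable across runs and platforms.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


class HillParams(BaseModel):
    """Cooperative-binding (Hill) dose-response parameters.

    The steady emission rate at autoinducer concentration ``ai`` (nM) is
    ``i_base + (i_max - i_base) * ai**n / (k_eq**n + ai**n)``.
    """

    model_config = {"extra": "forbid"}

    k_eq: float = Field(gt=0, description="half-maximal AI concentration (nM)")
    hill_n: float = Field(gt=0, description="Hill cooperativity coefficient")
    i_max: float = Field(ge=0, description="saturating emission rate (photons/min)")
    i_base: float = Field(ge=0, default=0.0, description="basal emission rate (photons/min)")

    @model_validator(mode="after")
    def _ordered(self) -> "HillParams":
        if self.i_max < self.i_base:
            raise ValueError("i_max must be >= i_base")
        return self


class CellPhenotype(BaseModel):
    """One cell's response parameters.

    amplitude : steady emission rate reached at the ambient AI (photons/min)
    onset_center : time of half-rise of the logistic response (min)
    onset_width : logistic rise timescale (min)
    init_level : emission rate at t = 0 (photons/min)
    fluct_sd : stationary sd of the log-scale OU fluctuation (dimensionless)
    fluct_tau : correlation time of the fluctuation (min)
    """

    model_config = {"extra": "forbid"}

    amplitude: float = Field(ge=0)
    onset_center: float
    onset_width: float = Field(gt=0)
    init_level: float = Field(ge=0)
    fluct_sd: float = Field(ge=0)
    fluct_tau: float = Field(gt=0)


class EnsembleModel(BaseModel):
    """Population model from which per-cell phenotypes are drawn.

    The ensemble-mean steady amplitude at AI concentration ``ai`` equals the
    Hill curve ``bulk_response(ai, hill)`` by construction: the induced
    component (amplitude minus basal) is log-normal with log-scale sd
    ``amp_logsd`` and arithmetic mean ``bulk_response(ai) - i_base``, so the
    basal rate is homogeneous while the induced response is heterogeneous.
    Onset times are uniform on ``onset_range`` and independent of amplitude.
    """

    model_config = {"extra": "forbid"}

    hill: HillParams
    amp_logsd: float = Field(ge=0, default=0.85)
    onset_range: tuple[float, float] = (30.0, 210.0)
    onset_width: float = Field(gt=0, default=25.0)
    init_level: float | None = Field(default=None, description="defaults to hill.i_base")
    fluct_sd: float = Field(ge=0, default=0.15)
    fluct_tau: float = Field(gt=0, default=30.0)
    n_cells: int = Field(ge=0, default=100)
    seed: int = 0

    @model_validator(mode="after")
    def _range_ok(self) -> "EnsembleModel":
        lo, hi = self.onset_range
        if lo < 0 or hi < lo:
            raise ValueError("onset_range must satisfy 0 <= lo <= hi")
        return self


class ImagingModel(BaseModel):
    """Detector and optics model for rendered frames.

    Background counts are additive Gaussian per pixel; ``bg_sd`` defaults to
    the value calibrated so that empty-region photometry shows the expected
    detection floor (roughly 20 photons/min peak-to-peak per frame).
    """

    model_config = {"extra": "forbid"}

    pixel_scale: float = Field(gt=0, default=0.278, description="um per pixel")
    frame_shape: tuple[int, int] = (256, 256)
    exposure: float = Field(gt=0, default=10.0, description="minutes")
    frame_interval: float = Field(gt=0, default=10.0, description="minutes between exposures")
    psf_sd: float = Field(ge=0, default=1.0, description="optical blur sd (pixels)")
    bg_mean: float = Field(ge=0, default=100.0, description="background counts per pixel")
    bg_sd: float = Field(ge=0, default=1.75, description="background noise sd per pixel")
    counts_per_photon: float = Field(gt=0, default=1.0)


@dataclass
class CellGeometry:
    """A rod (spherocylinder) footprint: centroid, orientation and size."""

    centroid: tuple[float, float]  # (row, col) pixels
    angle: float                   # radians, from +col axis
    length_um: float
    width_um: float


@dataclass
class SyntheticScene:
    """Cell geometries, phenotypes and the ground-truth photon ledger.

    ``ledger[cell, frame]`` records the true emitted photon count of each
    cell in each luminescence exposure; ``true_rates[cell, frame]`` the true
    underlying emission rate (photons/min) at the frame start.
    """

    geometries: list[CellGeometry]
    phenotypes: list[CellPhenotype]
    imaging: ImagingModel
    ledger: dict = field(default_factory=dict)        # (cell_idx, frame_idx) -> photons
    true_rates: dict = field(default_factory=dict)    # (cell_idx, frame_idx) -> photons/min

    @property
    def n_cells(self) -> int:
        return len(self.geometries)

    def footprint_bounds_ok(self) -> bool:
        nr, nc = self.imaging.frame_shape
        half = max((g.length_um / 2 + g.width_um) / self.imaging.pixel_scale
                   for g in self.geometries) if self.geometries else 0
        return all(
            half <= g.centroid[0] <= nr - 1 - half and half <= g.centroid[1] <= nc - 1 - half
            for g in self.geometries
        )


def bulk_response(ai_levels, hill: HillParams) -> np.ndarray:
    """Ensemble-mean steady emission rate at each AI concentration (nM)."""
    scalar = np.isscalar(ai_levels) or np.ndim(ai_levels) == 0
    ai = np.atleast_1d(np.asarray(ai_levels, dtype=float))
    if np.any(ai < 0):
        raise ValueError("AI concentrations must be >= 0")
    # occupancy ai**n / (k**n + ai**n) computed as 1/(1 + (k/ai)**n) on the
    # positive entries only, which is stable for ai -> 0 and ai -> inf
    occ = np.zeros_like(ai)
    pos = ai > 0
    with np.errstate(over="ignore"):
        occ[pos] = 1.0 / (1.0 + (hill.k_eq / ai[pos]) ** hill.hill_n)
    out = hill.i_base + (hill.i_max - hill.i_base) * occ
    return float(out[0]) if scalar else out


def draw_ensemble(model: EnsembleModel, ai: float) -> list[CellPhenotype]:
    """Draw ``model.n_cells`` phenotypes for an ensemble held at ``ai`` nM.

    Induced amplitudes (above basal) are log-normal with arithmetic mean
    ``bulk_response(ai) - i_base`` and log-sd ``amp_logsd``; the degenerate
    case ``amp_logsd = 0`` returns amplitudes exactly on the Hill curve.
    Reproducible for a given ``model.seed``.
    """
    if ai < 0:
        raise ValueError("ai must be >= 0")
    rng = substream(model.seed, 0)
    mean_total = float(bulk_response(ai, model.hill))
    mean_induced = mean_total - model.hill.i_base
    n = model.n_cells
    if model.amp_logsd > 0 and mean_induced > 0:
        # arithmetic mean m of LogNormal(mu, s): m = exp(mu + s^2/2)
        mu = math.log(mean_induced) - 0.5 * model.amp_logsd**2
        induced = rng.lognormal(mean=mu, sigma=model.amp_logsd, size=n)
    else:
        induced = np.full(n, max(mean_induced, 0.0))
    onsets = rng.uniform(model.onset_range[0], model.onset_range[1], size=n)
    init = model.hill.i_base if model.init_level is None else model.init_level
    return [
        CellPhenotype(
            amplitude=model.hill.i_base + induced[i],
            onset_center=onsets[i],
            onset_width=model.onset_width,
            init_level=init,
            fluct_sd=model.fluct_sd,
            fluct_tau=model.fluct_tau,
        )
        for i in range(n)
    ]


def _ou_path(rng: np.random.Generator, times: np.ndarray, sd: float, tau: float) -> np.ndarray:
    """Exact stationary Ornstein-Uhlenbeck sample on an arbitrary time grid."""
    x = np.empty_like(times)
    x[0] = rng.normal(0.0, sd)
    for k in range(1, len(times)):
        rho = math.exp(-(times[k] - times[k - 1]) / tau)
        x[k] = rho * x[k - 1] + sd * math.sqrt(1.0 - rho * rho) * rng.normal()
    return x


def simulate_trajectories(
    phenotypes: list[CellPhenotype],
    timegrid,
    seed: int = 0,
) -> np.ndarray:
    """True emission-rate time series, one row per cell (photons/min).

    rate_i(t) = [init + (amplitude - init) * logistic((t - onset)/width)]
                * exp(x_i(t)),
    with x_i a stationary OU process (mean 0, sd fluct_sd, correlation time
    fluct_tau). ``fluct_sd = 0`` recovers the deterministic logistic exactly.
    """
    t = np.asarray(timegrid, dtype=float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("timegrid must be strictly increasing")
    rates = np.empty((len(phenotypes), len(t)))
    for i, ph in enumerate(phenotypes):
        det = ph.init_level + (ph.amplitude - ph.init_level) * expit(
            (t - ph.onset_center) / ph.onset_width
        )
        if ph.fluct_sd > 0:
            rng = substream(seed, 1, i)
            det = det * np.exp(_ou_path(rng, t, ph.fluct_sd, ph.fluct_tau))
        rates[i] = np.maximum(det, 0.0)
    return rates


# ---------------------------------------------------------------------------
# Scene construction and rendering


def _rod_footprint(shape, geom: CellGeometry, pixel_scale: float) -> np.ndarray:
    """Anti-aliased occupancy weights of a rod (capsule) on the pixel grid."""
    half_len_px = max(geom.length_um / 2 / pixel_scale - geom.width_um / 2 / pixel_scale, 0.0)
    half_wid_px = geom.width_um / 2 / pixel_scale
    r0, c0 = geom.centroid
    pad = int(math.ceil(half_len_px + half_wid_px + 2))
    rlo, rhi = int(r0) - pad, int(r0) + pad + 1
    clo, chi = int(c0) - pad, int(c0) + pad + 1
    if rlo < 0 or clo < 0 or rhi > shape[0] or chi > shape[1]:
        raise ValueError("cell footprint extends outside the frame")
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    # distance from pixel center to the rod's axis segment
    dr, dc = rr - r0, cc - c0
    ax_r, ax_c = math.sin(geom.angle), math.cos(geom.angle)
    along = dr * ax_r + dc * ax_c
    along_clamped = np.clip(along, -half_len_px, half_len_px)
    dist = np.hypot(dr - along_clamped * ax_r, dc - along_clamped * ax_c)
    weights = np.clip(half_wid_px + 0.5 - dist, 0.0, 1.0)
    out = np.zeros(shape)
    out[rlo:rhi, clo:chi] = weights
    return out


def make_scene(
    n_cells: int,
    imaging: ImagingModel,
    phenotypes: list[CellPhenotype],
    seed: int = 0,
    min_separation_px: float | None = None,
) -> SyntheticScene:
    """Place ``n_cells`` well-separated rods (3-5 um long) in the frame."""
    if len(phenotypes) != n_cells:
        raise ValueError("need one phenotype per cell")
    rng = substream(seed, 2)
    nr, nc = imaging.frame_shape
    max_half_px = (5.0 / 2 + 1.0) / imaging.pixel_scale
    if min_separation_px is None:
        min_separation_px = 2 * max_half_px + 4
    margin = max_half_px + 2
    if nr - 2 * margin <= 0 or nc - 2 * margin <= 0:
        raise ValueError("frame too small for any cell")
    centroids: list[tuple[float, float]] = []
    geoms: list[CellGeometry] = []
    attempts = 0
    while len(geoms) < n_cells:
        attempts += 1
        if attempts > 1000 * max(n_cells, 1):
            raise RuntimeError("could not place cells without overlap; enlarge frame_shape")
        r = rng.uniform(margin, nr - 1 - margin)
        c = rng.uniform(margin, nc - 1 - margin)
        if any((r - r2) ** 2 + (c - c2) ** 2 < min_separation_px**2 for r2, c2 in centroids):
            continue
        centroids.append((r, c))
        geoms.append(
            CellGeometry(
                centroid=(r, c),
                angle=rng.uniform(0, math.pi),
                length_um=rng.uniform(3.0, 5.0),
                width_um=1.0,
            )
        )
    return SyntheticScene(geometries=geoms, phenotypes=phenotypes, imaging=imaging)


def auto_frame_shape(n_cells: int, pixel_scale: float = 0.278) -> tuple[int, int]:
    """Frame side large enough to place ``n_cells`` non-overlapping rods."""
    spacing = 2 * ((5.0 / 2 + 1.0) / pixel_scale) + 4
    side = int(math.ceil(math.sqrt(max(n_cells, 1) * spacing**2 * 2.8))) + 2 * int(spacing)
    return (max(side, 128), max(side, 128))


def render_frame_pair(
    scene: SyntheticScene,
    rates,
    seed: int = 0,
    frame_index: int = 0,
):
    """Render one (dark-field, luminescence) exposure pair.

    The luminescence frame deposits, for each cell, a Poisson photon count
    with mean rate x exposure over the rod footprint, blurs by the PSF,
    applies the detector gain and adds Gaussian background. True photon
    counts are recorded in the scene ledger. The dark-field frame shows
    bright rods on a dark background for localization.

    Returns ``(darkfield, luminescence)`` as float arrays of detector counts.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) != scene.n_cells:
        raise ValueError("rates must match the number of cells in the scene")
    imaging = scene.imaging
    rng = substream(seed, 3, frame_index)
    shape = imaging.frame_shape

    photon_img = np.zeros(shape)
    df_img = np.zeros(shape)
    for i, geom in enumerate(scene.geometries):
        fp = _rod_footprint(shape, geom, imaging.pixel_scale)
        total = fp.sum()
        n_photons = int(rng.poisson(rates[i] * imaging.exposure))
        scene.ledger[(i, frame_index)] = n_photons
        scene.true_rates[(i, frame_index)] = float(rates[i])
        if total > 0 and n_photons > 0:
            photon_img += n_photons * fp / total
        df_img += 1000.0 * fp

    if imaging.psf_sd > 0:
        photon_img = ndimage.gaussian_filter(photon_img, imaging.psf_sd)
        df_img = ndimage.gaussian_filter(df_img, imaging.psf_sd)

    lum = imaging.counts_per_photon * photon_img + rng.normal(
        imaging.bg_mean, imaging.bg_sd, size=shape
    )
    dark = df_img + rng.normal(10.0, 2.0, size=shape)
    return np.maximum(dark, 0.0), np.maximum(lum, 0.0)


def render_stack(
    scene: SyntheticScene,
    rate_matrix,
    seed: int = 0,
):
    """Render alternating dark-field / luminescence frames for all time points.

    ``rate_matrix`` has shape (n_cells, n_frames). Returns
    ``(darkfield_frames, luminescence_frames)`` lists of count arrays.
    """
    rate_matrix = np.asarray(rate_matrix, dtype=float)
    dark_frames, lum_frames = [], []
    for j in range(rate_matrix.shape[1]):
        dark, lum = render_frame_pair(scene, rate_matrix[:, j], seed=seed, frame_index=j)
        dark_frames.append(dark)
        lum_frames.append(lum)
    return dark_frames, lum_frames


def stable_source_fixture(
    n_particles: int,
    level: float,
    imaging: ImagingModel,
    seed: int = 0,
    n_frames: int = 25,
):
    """Point-like emitters of constant true rate, for stability controls.

    Emulates micron-sized fluorescent beads imaged with the same photometry:
    no onset, no intrinsic fluctuation; only detection noise remains.
    Returns ``(scene, times, dark_frames, lum_frames)``.
    """
    if level <= 0:
        raise ValueError("level must be > 0")
    phen = [
        CellPhenotype(
            amplitude=level, onset_center=0.0, onset_width=1.0,
            init_level=level, fluct_sd=0.0, fluct_tau=1.0,
        )
        for _ in range(n_particles)
    ]
    scene = make_scene(n_particles, imaging, phen, seed=seed)
    # spheres ~1 um: round footprint
    for g in scene.geometries:
        g.length_um = 1.0
        g.width_um = 1.0
    times = np.arange(n_frames) * imaging.frame_interval
    rates = np.full((n_particles, n_frames), float(level))
    dark, lum = render_stack(scene, rates, seed=seed)
    return scene, times, dark, lum
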
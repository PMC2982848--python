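# Methods

This note documents the models, algorithms and numerical choices behind
`luxtrace`, in the order data flows through the pipeline.

## Synthetic single-cell ensembles

The generator produces the statistical structure of low-light microscopy of
quorum-sensing bacteria adhered in a perfusion chamber.

**Dose–response.** The ensemble-mean steady emission rate at autoinducer
concentration `ai` (nM) is the cooperative-binding (Hill) curve
`I(ai) = i_base + (i_max − i_base)·ai^n/(k_eq^n + ai^n)`. Two named
fixtures are packaged: `MJ11-bulk` (k_eq = 200 nM, n = 2.6) describing a
bulk-culture response, and `MJ11-single` (k_eq = 120 nM, n = 2.7,
i_base = 2, i_max = 38 photons/min) describing single-cell ensembles. The
saturating rate of 38 photons/min places individual amplitudes
predominantly in the 10–100 photons/min range actually detected from
single cells, with a log-normal tail reaching a few hundred.

**Per-cell heterogeneity.** A cell's steady amplitude is
`i_base + X` with `X` log-normal: log-scale sd `amp_logsd = 0.85` and
arithmetic mean equal to `I(ai) − i_base`, so the ensemble mean sits on the
Hill curve by construction at every concentration (verified by Monte Carlo
against the curve within 3 standard errors at 10⁴ draws). The shifted form
(basal rate homogeneous, induced response heterogeneous) makes the zero-AI
ensemble exactly basal while giving full-induction amplitude cv
`≈ sqrt(exp(0.85²) − 1) ≈ 1` and roughly a quarter of cells below the
15 photons/min detection threshold — the two heterogeneity calibration
targets. Amplitude and onset time are drawn independently; no correlation
between them is modeled because none is established for this system.

**Kinetics.** Each cell rises logistically from `init_level` (default:
basal) to its amplitude with half-rise at `onset_center` — uniform on
[30, 210] min, reflecting the very broad, flat observed onset
distributions — and rise timescale `onset_width = 25` min (the per-cell
kinetic law is not constrained by data; a logistic is the simplest
saturating form). On top of the deterministic rise, the rate is multiplied
by `exp(x(t))` with `x` a stationary Ornstein–Uhlenbeck process of sd 0.15
and correlation time 30 min, reproducing ~20–40% brightness fluctuations on
half-hour timescales. The OU update uses the exact discretization
`x(t+Δ) = x(t)·e^(−Δ/τ) + sd·sqrt(1−e^(−2Δ/τ))·ξ`, so statistics are
correct on any time grid and `fluct_sd = 0` recovers the deterministic
trajectory exactly.

**Imaging.** Cells are rods 3–5 µm long and 1 µm wide at 0.278 µm/pixel,
placed with non-overlapping footprints (frames are auto-enlarged when an
ensemble would not fit). Each luminescence exposure (default 10 min, one
per 10-min interval, alternating with short dark-field exposures) deposits
a Poisson photon count with mean rate × exposure uniformly over the rod
footprint (anti-aliased), blurs it with a Gaussian PSF (sd 1 pixel),
applies the detector gain (default 1 count/photon) and adds Gaussian
background (mean 100, sd 1.75 counts/pixel). The true photon count of
every (cell, frame) pair is recorded in a ledger, which is the oracle for
all quantification tests. `bg_sd = 1.75` is calibrated so that applying
the full quantification to cell-free regions spreads over roughly
20 photons/min peak-to-peak per frame — the documented detection floor of
the measurement being emulated. The background model is deliberately
simple: no hot pixels, no intensifier gain map, no focus drift, no cell
growth or division. Consequently, passing tests demonstrate correctness of
the algorithms under the stated statistical model, not robustness to every
instrumental pathology of real intensified-CCD data.

**Determinism.** All randomness derives from one master seed through
`numpy` `SeedSequence` spawn keys (a stable (seed, purpose, index) →
stream mapping), so scenes, trajectories and frames are bit-reproducible.

## Photometry

**Localization.** Dark-field frames are thresholded at the robust
background level (median + 6×1.4826·MAD); connected components whose major
axis is 8–25 px (2.2–7 µm) become cells. Shorter components are noise;
longer ones are flagged `merged_or_too_long` and excluded — touching cells
are discarded rather than split. The region of interest (ROI) is the
component bounding box padded by 6 px; coordinates are 0-based, row-major,
half-open.

**Stability.** Successive dark-field frames are compared by sub-pixel
phase cross-correlation (global drift) and by matching detected centroids
(per-cell displacement); cells moving more than 0.6 µm are flagged and
excluded from trajectories. Drifted cells are excluded, never corrected.

**Quantification.** For each cell and luminescence frame: crop the ROI,
2×2-bin by block *sum* (sums preserve photon bookkeeping; a trailing odd
row/column is dropped), histogram the binned values in integer bins of
width 1, and subtract a Gaussian background model:

- The Gaussian is fit by least squares to the lower portion of the
  histogram — the bins at or below the (lightly smoothed) mode plus the
  near-symmetric bins above it below mode + 1 initial-sd — because the
  background dominates the low side while cell photons contaminate only
  the upper tail. The fit is seeded with a MAD-based width estimate and
  bounded (mean within ±3 initial-sd of the mode, width in [0.3, 4]×) so
  sparse histograms cannot send it off to degenerate optima.
- The photon count is the intensity-weighted signed residual
  `Σ_b (h_b − g_b)(c_b − µ)/gain`, divided by the exposure to give
  photons/minute. The signed residual is unbiased on cell-free regions (in
  expectation it equals exactly the total signal above background);
  optional per-bin clipping at zero (`clip_residual=True`) is retained for
  comparison but adds a small positive null bias.
- Because the estimator multiplies any error in the background mean µ by
  the number of ROI pixels, µ must be essentially exact. In pipeline runs
  the background is therefore fit once per *frame* from all cell-free
  pixels (every ROI masked out; tens of thousands of pixels pin µ to
  ~0.01 counts) and rescaled to each ROI by pixel count. When no
  frame-level fit is available, `quantify_cell` falls back to fitting the
  ROI's padding margin only, excluding the detected cell's core box grown
  by one binned pixel, so the blurred cell skirt cannot drag µ upward.
  Both choices exist because a per-region fit on ~10² pixels was measured
  (against the generator ledger) to produce a few-photons/min systematic
  deficit — an 8–10% error on typical 25 photons/min signals that directly
  inflates every mean-normalized statistic downstream.

Measured rates are reported as-is, including small negative values on
empty regions; flooring at zero is left to presentation so the null
calibration stays testable. Against the ground-truth ledger the estimator
is linear with slope 1.00 ± few×10⁻³ and intercept within the detection
floor over 20–300 photons/min.

**Noise floor.** Applying the identical procedure to regions containing no
cells yields the per-frame measurement floor (sd and peak-to-peak); the sd
is attached to every measurement as its uncertainty.

## Trajectory analysis

Per-cell series are smoothed with a Gaussian kernel of σ = 10 min
evaluated at the actual sample-time offsets, truncated at ±3σ and
renormalized per point — this handles irregular sampling and boundaries,
preserves constants exactly and affine trends in the interior.

The onset time t½ is the earliest time the smoothed series crosses the
midpoint between `i_initial` (smoothed value at the first frame) and
`i_final` (mean of smoothed values within 10 min of the last frame),
linearly interpolated between frames; the first-crossing rule makes t½
single-valued on noisy, non-monotonic trajectories, and it is invariant
under positive affine rescaling of the whole trajectory. The final window
of 10 min (two frames at the usual cadence) averages down single-frame
noise without underestimating the final level of late-rising cells; a
cell whose net change does not exceed 3× the noise floor is classified
`flat` and gets no onset time, and falling trajectories get a defined t½
by the same midpoint rule with direction `falling`. On noiseless logistic
ensembles observed long enough for the latest onsets to complete
(≈ 280 min for onsets up to 210 min), ≥ 90% of recovered t½ fall within
±10 min of the true half-rise time; the residual misses are cells whose
rise overlaps the observation boundaries, for which the halfway-level
definition itself differs from the underlying logistic midpoint.

A cell is `dark` at time t if its smoothed level at the nearest frame is
at or below the detection threshold (default 15 photons/min) — consistent
with no resolvable emission.

## Ensemble statistics

- **Per-cell level**: time-average of the smoothed rate over
  t ∈ (100, 250] min — emission recorded after the ensemble has responded.
- **Brightness distributions**: histogram plus quartiles (linear
  interpolation between order statistics) of smoothed levels at a frame.
- **cv** = sample sd (n−1) / mean of per-cell levels; errors if the mean
  is non-positive.
- **Hill fit**: nonlinear least squares of per-level mean against the
  cooperative-binding curve; initialization i_base = min level,
  i_max = max level, k_eq = level nearest half-range, n = 2; tolerances
  10⁻¹²; parameter standard errors from the local curvature. The
  half-maximal concentration is bounded to 20× the largest sampled
  concentration and the cooperativity to 15 — beyond the sampled range and
  sampling resolution those parameters are unidentifiable, and unbounded
  noisy fits can run away. Unweighted by default with an optional
  1/n_cells weighting; fits lacking half-maximum bracketing, failing to
  converge, or placing k_eq >10× outside the sampled range are flagged,
  not raised. On noiseless model-generated data the fit recovers the
  generating parameters to machine-level precision.
- **σ_d(τ)**: for each lag τ (a multiple of the frame interval), pairs
  (I(t), I(t+τ)) are pooled over all cells and frames with t ≥ 100 min, an
  ordinary least-squares line is drawn through the pooled scatter, and
  σ_d is the sample sd of the vertical distances from the line. Lags with
  fewer than 10 pairs are omitted with a warning; a per-cell variant is
  available behind a flag. σ_d is invariant to a common additive offset
  and scales linearly with a common factor; Gaussian smoothing produces
  the expected dip at τ equal to one kernel width.
- **Median-normalized histograms** divide levels by their median (which
  then equals 1 exactly) and are invariant to rescaling.

No hypothesis tests are performed anywhere; all outputs are descriptive
statistics and fits, so no multiple-testing control is needed.

## Chamber transport

The perfusion chamber (two 25 mm coverslips 5 mm apart, 0.2 ml/hr flow) is
reduced to a 2-D channel cross-section (along-flow x, wall-normal z) with
a plane-Poiseuille profile whose mean velocity is Q/(gap·width); the
transverse width enters only there. This is the standard tractable
reduction and is conservative: it allows no lateral spreading of released
autoinducer. The steady equation 0 = D∇²c − u(z)∂c/∂x is discretized by a
finite-volume scheme — central diffusion, upwind advection — and solved
directly. Boundary conditions: c = 0 at the inflow, advective outflow
(zero diffusive flux), zero flux at the top wall, and a constant molar
influx over the cell patch on the bottom wall, with each boundary cell's
source weighted by its exact overlap with the patch so the injected mass
is grid-independent. Source strength: 1000 cells (a generous upper
estimate for "a few cells over a few mm²") × 10⁻²¹ g/s each ÷ 213.2 g/mol
(3OC6HSL), spread over a 2 mm patch; diffusivity 100 µm²/s. The
finite-volume form conserves mass to solver precision (balance closed to
~10⁻¹³ at the default grid) and the upwind/central operator is an
M-matrix, so the discrete solution is non-negative. The default grid is
250×100 cells (gap resolved by 100 points, patch by 20); refinement
changes the window maximum by < 1%. The window concentration is the
bottom-row cell value extrapolated to the wall with the imposed flux
(c_wall = c + J·Δz/2D). The default configuration yields ≈ 0.9 pM at the
window — consistent with a Lévêque boundary-layer estimate
c ~ J·(Dx/γ)^⅓/D ≈ 0.7 pM — three orders of magnitude below induction
levels. Validation includes a zero-flow half-space configuration matched
against the constant-flux-disc formula c = Q/(4·D·a_eff) (geometry chosen
from the 2-D strip-source Green's function so the strip and disc
predictions coincide) and a thin-slab 1-D closed form matched to < 1%.

## Replication of stochastic summaries

Two headline quantities are intrinsically noisy at the study's ensemble
sizes: the pipeline-recovered equilibrium constant (30 cells per level,
8 levels; sampling sd ≈ 25 nM because every level mean carries cv ≈ 1
heterogeneity over 30 cells) and the full-induction cv and dark fraction
(200 cells; cv sampling spread ≈ ±0.15 from the log-normal tail). The
acceptance computations therefore run five independent replicate image
sets and report the median fit (K_eq) or pool the per-cell levels and
dark calls (cv, dark fraction). Per-ensemble conditions are untouched;
replication only narrows the sampling noise of the reported summary.
Problem sizes used throughout: 8 AI levels × 30 cells × 26 frame pairs
per dose-response replicate; 200 cells × 26 frame pairs per heterogeneity
replicate; 250×100 finite-volume cells for transport.

## Known limitations

- The detector model is additive Gaussian background plus Poisson signal;
  real intensified cameras add multiplicative intensifier noise, hot
  pixels and spatial gain structure that the frame-level background fit
  would only partly absorb.
- Cells neither grow, divide, move nor defocus; the stability check is
  exercised only by constructed displacements.
- The onset distribution, logistic rise and amplitude–onset independence
  are phenomenological choices, constrained by summary statistics rather
  than by single-cell kinetic data.
- The transport solve is steady-state and 2-D; no time-dependent washout
  and no coupling of self-produced AI back into the response simulator.
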
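# luxtrace

Single-cell bioluminescence photometry and quorum-sensing response analysis.

Wild-type *Vibrio fischeri* cells held in a perfusion chamber at a fixed
autoinducer (AI, 3OC6HSL) concentration emit only tens of photons per minute
each, collected in ten-minute exposures on an intensified camera. `luxtrace`
implements the complete analysis chain for such data, plus a ground-truthed
synthetic-data generator so every stage is testable without any experimental
download:

- **synthetic** — renders dark-field / luminescence frame-pair stacks of
  rod-shaped cells (0.278 µm/pixel) whose per-cell emission follows a
  logistic induction response with log-normally heterogeneous amplitudes,
  broadly distributed onset times, and multiplicative Ornstein–Uhlenbeck
  fluctuations; the ensemble-mean steady response versus AI follows a
  cooperative-binding (Hill) curve
  `I(AI) = I_base + (I_max − I_base)·AI^n / (K_eq^n + AI^n)`.
- **photometry** — locates immobile cells on dark-field frames, then counts
  each cell's photons from a luminescence frame by 2×2-binning a small
  rectangular region, fitting a Gaussian to the lower portion of its
  brightness histogram (the detector background), and summing the
  intensity-weighted residual above that background.
- **trajectories** — per-cell emission-rate time series, Gaussian temporal
  filtering (σ = 10 min), onset times t½ (first crossing of the halfway
  level between initial and final emission) and dark/bright classification
  against the ~15 photons/min detection floor.
- **ensemble** — brightness histograms and percentile bands over time,
  coefficient of variation (cv = sd/mean), nonlinear least-squares Hill
  fits with parameter standard errors, median-normalized distributions, and
  the σ_d(τ) temporal-divergence statistic.
- **microenv** — a steady-state advection–diffusion solve of the perfusion
  chamber showing that AI released by the adhered cells themselves stays
  far below induction levels at the observation window.

## Worked example

Simulate a 20-cell ensemble at saturating AI (1000 nM), quantify the
rendered stacks, and analyze the trajectories:

```python
from pathlib import Path
from luxtrace.config import RunConfig
from luxtrace.pipeline import simulate_run, quantify_run, analyze_run, run_microenv

cfg = RunConfig(seed=11)
cfg = cfg.model_copy(update={"ensemble": cfg.ensemble.model_copy(update={"n_cells": 20})})
run = simulate_run(cfg, Path("demo/run"), ai_nM=1000.0)   # TIFF stacks + truth ledger
csv = quantify_run(run, cfg)                              # per-cell rates per frame
res = analyze_run([csv], cfg, Path("demo/analysis"))
print(res["dose_response"])
```

which prints

```
 ai_nM  mean_level  n_cells       cv
1000.0   25.717422       20 0.736714
```

— the ensemble's mean steady emission (time-averaged over t > 100 min) is
~26 photons/min with large cell-to-cell variability (cv ≈ 0.7 in this small
sample; ≈ 1 for large ensembles). The onset table shows the kinetic
heterogeneity — half-rise times scattered from ~50 to ~190 minutes after AI
introduction, with non-responding cells flagged `flat`:

```
 ai_nM  cell_id  t_half_min direction  i_initial   i_final
1000.0        0  104.026606    rising   0.442217 11.573281
1000.0        1  187.991364    rising   5.435034 18.221495
1000.0        2   51.879341    rising   7.785065 17.400929
1000.0        3         NaN      flat  -1.692600  3.359590
```

The chamber transport check (`run_microenv(cfg)`) reports

```
max_at_window_pM 0.888   (mass balance error 7e-14)
```

i.e. self-produced AI accumulates to under 1 pM at the window — three
orders of magnitude below the ~100 nM induction scale — so the flowing
medium fully controls the signal the cells experience.

The same stages are available from the shell:

```
luxtrace simulate --out demo/run --ai 1000 --n-cells 20 --seed 11
luxtrace quantify --in demo/run
luxtrace analyze --in demo/run/measurements.csv --out demo/analysis
luxtrace microenv
luxtrace all --out demo --seed 11        # 8 AI levels + dose-response fit
```

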
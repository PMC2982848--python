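"""Reproductions of the study's in-silico experiments at full pipeline depth.

These helpers run the simulate -> quantify -> analyze chain under the
standard study conditions (30 cells per AI level for the dose-response;
200 fully induced cells for the heterogeneity statistics) and aggregate
over independent replicate ensembles. Replication narrows the sampling
noise of stochastic summary statistics (a fitted equilibrium constant, a
coefficient of variation) around their ensemble values without touching
the per-ensemble conditions.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import io
from .config import RunConfig
from .ensemble import coefficient_of_variation, per_cell_level
from .pipeline import analyze_run, quantify_run, simulate_run
from .trajectories import build_trajectories, classify_dark

__all__ = ["DOSE_AI_LEVELS", "dose_response_experiment", "full_induction_experiment"]

#: eight AI levels spanning 0-1000 nM, concentrated around the half-maximal
#: concentration of the single-cell fixture for good identifiability
DOSE_AI_LEVELS = [0.0, 60.0, 90.0, 120.0, 160.0, 220.0, 400.0, 1000.0]


def _replicate_seeds(master_seed: int, n_replicates: int, offset: int = 0) -> list[int]:
    return [(int(master_seed) + offset + i) % (2**31 - 1) for i in range(n_replicates)]


def dose_response_experiment(
    master_seed: int,
    n_replicates: int = 5,
    n_cells: int = 30,
    ai_levels: list[float] | None = None,
    work_dir: Path | None = None,
) -> dict:
    """Full-pipeline dose-response fits over replicate image sets.

    Each replicate renders ``n_cells`` cells at every AI level with the
    single-cell fixture, quantifies the stacks, fits the cooperative-binding
    model to the per-level means, and records the fitted parameters. Returns
    the per-replicate fits plus their medians.
    """
    ai_levels = ai_levels or DOSE_AI_LEVELS
    k_eqs, hill_ns = [], []
    for seed in _replicate_seeds(master_seed, n_replicates):
        cfg = RunConfig(seed=seed)
        cfg = cfg.model_copy(update={
            "ensemble": cfg.ensemble.model_copy(update={"n_cells": n_cells}),
            "ai_levels_nM": list(ai_levels)})
        with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
            tmp = Path(tmp)
            csvs = []
            for i, ai in enumerate(ai_levels):
                from .synthetic import substream
                level_seed = int(substream(cfg.seed, 7, i).integers(0, 2**31 - 1))
                run_dir = simulate_run(cfg, tmp / f"ai{ai:g}", ai_nM=ai, seed=level_seed)
                csvs.append(quantify_run(run_dir, cfg))
            results = analyze_run(csvs, cfg, tmp / "analysis", make_plots=False)
        fit = results["hill_fit"]
        k_eqs.append(fit.params.k_eq)
        hill_ns.append(fit.params.hill_n)
    return {
        "k_eq_per_replicate": k_eqs,
        "hill_n_per_replicate": hill_ns,
        "k_eq": float(np.median(k_eqs)),
        "hill_n": float(np.median(hill_ns)),
        "n_cells_total": n_cells * len(ai_levels) * n_replicates,
    }


def full_induction_experiment(
    master_seed: int,
    n_replicates: int = 5,
    n_cells: int = 200,
    ai_nM: float = 1000.0,
    dark_threshold: float = 15.0,
    dark_at: float = 240.0,
    work_dir: Path | None = None,
) -> dict:
    """Heterogeneity statistics of fully induced ensembles.

    Renders and quantifies ``n_replicates`` independent 200-cell ensembles
    at saturating AI, then pools the per-cell steady levels (time averages
    over t > 100 min) and the dark/bright calls at t = 240 min across
    replicates. Returns the pooled cv, pooled dark percentage, and the
    per-replicate values.
    """
    levels, dark_calls = [], []
    per_rep = []
    for seed in _replicate_seeds(master_seed, n_replicates):
        cfg = RunConfig(seed=seed)
        cfg = cfg.model_copy(update={
            "ensemble": cfg.ensemble.model_copy(update={"n_cells": n_cells})})
        with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
            run_dir = simulate_run(cfg, Path(tmp) / "run", ai_nM=ai_nM)
            df = io.read_csv(quantify_run(run_dir, cfg))
        trajs = build_trajectories(df, filter_sd=cfg.trajectory.filter_sd_min)
        rep_levels = [per_cell_level(tr) for tr in trajs]
        rep_dark = [classify_dark(tr, dark_threshold, dark_at) == "dark" for tr in trajs]
        levels.extend(rep_levels)
        dark_calls.extend(rep_dark)
        per_rep.append({
            "cv": coefficient_of_variation(rep_levels),
            "dark_percent": 100.0 * float(np.mean(rep_dark)),
            "n_cells": len(trajs),
        })
    return {
        "cv": coefficient_of_variation(levels),
        "dark_percent": 100.0 * float(np.mean(dark_calls)),
        "per_replicate": per_rep,
        "n_cells_total": len(levels),
    }
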
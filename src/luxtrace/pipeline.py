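"""End-to-end orchestration: simulate -> quantify -> analyze -> microenv.

Each stage is a plain function over the library modules; the command-line
interface wraps these one-to-one. All stages are deterministic given the
run configuration and master seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as es
from . import io, photometry as ph
from . import trajectories as tj
from .config import RunConfig
from .fixtures import get_fixture
from .microenv import grid_convergence, solve_steady_state
from .synthetic import (
    auto_frame_shape,
    draw_ensemble,
    make_scene,
    render_stack,
    stable_source_fixture,
    substream,
)

log = logging.getLogger("luxtrace")

__all__ = ["simulate_run", "quantify_run", "analyze_run", "run_microenv", "run_all"]


def simulate_run(
    config: RunConfig,
    out_dir: Path,
    ai_nM: float = 1000.0,
    seed: int | None = None,
) -> Path:
    """Simulate one ensemble at a fixed AI level and write its image stacks.

    Writes ``darkfield.tif``, ``luminescence.tif``, frame metadata and the
    ground-truth ledger into ``out_dir``. The frame shape grows
    automatically when the configured one cannot hold ``n_cells`` separated
    rods.
    """
    seed = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    meta = {"seed": seed, "config_hash": io.config_hash(config), "ai_nM": ai_nM,
            "fixture": config.fixture or "custom"}
    imaging = config.imaging
    times = np.arange(0.0, config.duration_min + 1e-9, imaging.frame_interval)

    if config.fixture == "stable-source":
        fx = get_fixture("stable-source", seed=seed)
        fx["imaging"] = imaging
        scene, times, dark, lum = stable_source_fixture(n_frames=len(times), **fx)
        io.write_run(out_dir, dark, lum, times, imaging.exposure, scene, meta)
        log.info("simulated stable-source run: %d particles, %d frames",
                 scene.n_cells, len(times))
        return out_dir

    model = config.ensemble_for(seed=seed)
    phenotypes = draw_ensemble(model, ai_nM)
    needed = auto_frame_shape(model.n_cells, imaging.pixel_scale)
    if needed[0] > imaging.frame_shape[0]:
        imaging = imaging.model_copy(update={"frame_shape": needed})
        log.info("frame enlarged to %s for %d cells", needed, model.n_cells)
    rates = _simulate(phenotypes, times, seed)
    scene = make_scene(model.n_cells, imaging, phenotypes, seed=seed)
    dark, lum = render_stack(scene, rates, seed=seed)
    io.write_run(out_dir, dark, lum, times, imaging.exposure, scene, meta)
    log.info("simulated %s at %g nM: %d cells, %d frame pairs (seed %d)",
             config.fixture, ai_nM, model.n_cells, len(times), seed)
    return out_dir


def _simulate(phenotypes, times, seed):
    from .synthetic import simulate_trajectories

    return simulate_trajectories(phenotypes, times, seed=seed)


def quantify_run(run_dir: Path, config: RunConfig, out_csv: Path | None = None) -> Path:
    """Quantify every luminescence frame of a simulated/recorded run.

    Locates cells on the first dark-field frame, checks stability across
    all dark-field frames (drifted cells are flagged and excluded),
    estimates the noise floor from cell-free regions, then quantifies each
    (cell, frame) pair. Writes the measurement table.
    """
    run_dir = Path(run_dir)
    out_csv = Path(out_csv) if out_csv else run_dir / "measurements.csv"
    dark, lum, meta = io.read_run(run_dir)
    pc = config.photometry
    loc_kw = dict(min_length_px=pc.min_length_px, max_length_px=pc.max_length_px,
                  k_sd=pc.k_sd, margin=pc.margin)
    rois = ph.locate_cells(dark[0], **loc_kw)
    good = [r for r in rois if not r.excluded]
    log.info("located %d cells (%d excluded)", len(good), len(rois) - len(good))

    unstable: set[int] = set()
    for frame in dark[1:]:
        res = ph.check_stability(dark[0], frame, pixel_scale=config.imaging.pixel_scale,
                                 displacement_tol_um=pc.displacement_tol_um, **loc_kw)
        unstable.update(res.flagged)
    if unstable:
        log.info("flagged %d cells for movement", len(unstable))

    # one background fit per frame from all cell-free pixels: the detector
    # background is spatially uniform, and a frame-level mean estimated
    # from ~10^4 pixels avoids the per-region fit's sensitivity to faint
    # blurred cell light in the small padding margins
    try:
        frame_bgs = [ph.frame_background(f, rois) for f in lum]
    except ph.BackgroundFitError:
        frame_bgs = [None] * len(lum)

    empties = ph.sample_empty_rois(dark[0].pixels.shape, rois, n=pc.n_empty_rois,
                                   size=18, rng=substream(config.seed, 9))
    try:
        floor_sd, floor_ptp = ph.estimate_noise_floor(
            lum[: min(5, len(lum))], empties, gain=config.imaging.counts_per_photon,
            backgrounds=frame_bgs[: min(5, len(lum))])
    except ValueError:
        floor_sd = floor_ptp = float("nan")
    log.info("noise floor: sd %.1f, p2p %.1f photons/min", floor_sd, floor_ptp)

    rows = []
    for roi in good:
        excl = roi.cell_id in unstable
        for frame, frame_bg in zip(lum, frame_bgs):
            try:
                m = ph.quantify_cell(frame, roi, gain=config.imaging.counts_per_photon,
                                     noise_floor_sd=floor_sd,
                                     clip_residual=pc.clip_residual,
                                     background=frame_bg)
                rate = m.rate
                flag = "moved" if excl else ""
            except ph.BackgroundFitError as exc:
                rate, flag = float("nan"), f"fit_error:{exc}"
            r0, c0, r1, c1 = roi.rectangle
            rows.append({
                "cell_id": roi.cell_id, "t_start_min": frame.t_start,
                "rate_photons_per_min": rate, "uncertainty": floor_sd,
                "roi_row0": r0, "roi_col0": c0, "roi_row1": r1, "roi_col1": c1,
                "excluded": excl or rate != rate, "flag": flag,
            })
    cols = ["cell_id", "t_start_min", "rate_photons_per_min", "uncertainty",
            "roi_row0", "roi_col0", "roi_row1", "roi_col1", "excluded", "flag"]
    meta_out = {"seed": config.seed, "config_hash": io.config_hash(config),
                "ai_nM": meta.get("ai_nM", "nan"),
                "noise_floor_sd": floor_sd, "noise_floor_ptp": floor_ptp}
    io.write_csv(pd.DataFrame(rows, columns=cols), out_csv, meta_out)
    return out_csv


def analyze_run(
    measurement_csvs: list[Path],
    config: RunConfig,
    out_dir: Path,
    make_plots: bool = True,
) -> dict:
    """Trajectory and ensemble analysis over one or more quantified runs.

    Each measurement file is one ensemble at one AI level. Writes long-form
    trajectories, onset times, the dose-response table, the cooperative-
    binding fit report (when >= 4 AI levels are present), the sigma_d(tau)
    divergence curve and summary figures. Returns the key results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tcfg, scfg = config.trajectory, config.stats
    results: dict = {}
    traj_rows, onset_rows, level_rows = [], [], []
    points = []
    trajs_by_level: dict[float, list] = {}

    for csv in measurement_csvs:
        csv = Path(csv)
        df = io.read_csv(csv)
        meta = io.read_csv_meta(csv)
        ai = float(meta.get("ai_nM", "nan"))
        floor = float(meta.get("noise_floor_sd", "nan"))
        trajs = tj.build_trajectories(df, filter_sd=tcfg.filter_sd_min)
        trajs_by_level[ai] = trajs
        levels = []
        for tr in trajs:
            for k, t in enumerate(tr.times):
                traj_rows.append({"ai_nM": ai, "cell_id": tr.cell_id, "t_min": t,
                                  "raw": tr.raw[k], "smoothed": tr.smoothed[k]})
            if tr.times[-1] - tr.times[0] >= 150:
                o = tj.onset_time(tr, final_window=tcfg.final_window_min,
                                  noise_floor=0.0 if floor != floor else floor)
                onset_rows.append({"ai_nM": ai, "cell_id": o.cell_id,
                                   "t_half_min": o.t_half if o.t_half is not None else "",
                                   "direction": o.direction,
                                   "i_initial": o.i_initial, "i_final": o.i_final})
            try:
                lv = es.per_cell_level(tr, scfg.level_t_min, scfg.level_t_max)
            except ValueError:
                continue
            levels.append(lv)
            level_rows.append({"ai_nM": ai, "cell_id": tr.cell_id,
                               "level_photons_per_min": lv})
        if levels:
            points.append(es.DoseResponsePoint(ai=ai, per_cell_levels=np.array(levels)))

    meta = {"seed": config.seed, "config_hash": io.config_hash(config)}
    io.write_csv(pd.DataFrame(traj_rows), out_dir / "trajectories.csv", meta)
    io.write_csv(pd.DataFrame(onset_rows), out_dir / "onsets.csv", meta)
    io.write_csv(pd.DataFrame(level_rows), out_dir / "levels.csv", meta)

    dose_rows = []
    for p in sorted(points, key=lambda p: p.ai):
        row = {"ai_nM": p.ai, "mean_level": p.mean_level, "n_cells": p.n_cells}
        try:
            row["cv"] = es.coefficient_of_variation(p.per_cell_levels)
        except ValueError:
            row["cv"] = float("nan")
        dose_rows.append(row)
    io.write_csv(pd.DataFrame(dose_rows), out_dir / "dose_response.csv", meta)
    results["dose_response"] = pd.DataFrame(dose_rows)

    if len(points) >= 4:
        fit = es.fit_hill(points, weights=scfg.hill_weights)
        results["hill_fit"] = fit
        with open(out_dir / "hill_fit.txt", "w") as fh:
            fh.write(f"# seed: {config.seed}\n# config_hash: {meta['config_hash']}\n")
            fh.write(f"k_eq_nM      {fit.params.k_eq:.4g} +- {fit.stderr['k_eq']:.3g}\n")
            fh.write(f"hill_n       {fit.params.hill_n:.4g} +- {fit.stderr['hill_n']:.3g}\n")
            fh.write(f"i_max        {fit.params.i_max:.4g} +- {fit.stderr['i_max']:.3g}\n")
            fh.write(f"i_base       {fit.params.i_base:.4g} +- {fit.stderr['i_base']:.3g}\n")
            fh.write(f"rms_resid    {fit.rms_resid:.4g}\nconverged    {fit.converged}\n")
            fh.write(f"flags        {','.join(fit.flags) or 'none'}\n")
        log.info("cooperative-binding fit: K_eq=%.1f nM, n=%.2f",
                 fit.params.k_eq, fit.params.hill_n)
    else:
        log.warning("dose-response fit skipped: %d AI level(s), need >= 4", len(points))

    # temporal divergence on the densest level
    if trajs_by_level:
        ai_big = max(trajs_by_level, key=lambda a: len(trajs_by_level[a]))
        trajs = trajs_by_level[ai_big]
        if len(trajs) >= 2:
            curve = es.autocorrelation_divergence(trajs, scfg.taus_min,
                                                  t_min=scfg.level_t_min)
            io.write_csv(pd.DataFrame({
                "tau_min": curve.taus, "sigma_d": curve.sigma_d,
                "n_pairs": curve.n_pairs}), out_dir / "divergence.csv", meta)
            results["divergence"] = curve

    if make_plots:
        _plots(out_dir, trajs_by_level, results)
    return results


def _plots(out_dir: Path, trajs_by_level: dict, results: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if trajs_by_level:
        ai_big = max(trajs_by_level, key=lambda a: len(trajs_by_level[a]))
        trajs = trajs_by_level[ai_big]
        fig, ax = plt.subplots(figsize=(6, 4))
        for tr in trajs[:20]:
            ax.plot(tr.times, tr.smoothed, lw=1)
        ax.set(xlabel="time (min)", ylabel="emission (photons/min)",
               title=f"single-cell trajectories at {ai_big:g} nM AI")
        fig.savefig(out_dir / "trajectories.png", dpi=120)
        plt.close(fig)

        final = [tr.smoothed[-1] for tr in trajs]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.hist(final, bins=20)
        ax.set(xlabel="emission (photons/min)", ylabel="cells",
               title="final brightness distribution")
        fig.savefig(out_dir / "brightness_hist.png", dpi=120)
        plt.close(fig)

    if "hill_fit" in results:
        dr = results["dose_response"]
        fit = results["hill_fit"]
        from .synthetic import bulk_response
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(dr["ai_nM"], dr["mean_level"], "o", label="mean level")
        xs = np.linspace(0, max(dr["ai_nM"].max(), 1.0), 200)
        ax.plot(xs, bulk_response(xs, fit.params), "--",
                label=f"fit: K_eq={fit.params.k_eq:.0f} nM, n={fit.params.hill_n:.1f}")
        ax.set(xlabel="AI (nM)", ylabel="emission (photons/min)")
        ax.legend()
        fig.savefig(out_dir / "dose_response.png", dpi=120)
        plt.close(fig)


def run_microenv(config: RunConfig, out_dir: Path | None = None,
                 grid: tuple[int, int] = (250, 100), convergence: bool = True) -> dict:
    """Chamber transport solve with optional grid-convergence table."""
    field = solve_steady_state(config.chamber, grid)
    result = {"max_at_window_pM": field.max_at_window,
              "mass_balance_error": field.mass_balance_error}
    log.info("AI accumulation at window: %.3g pM (mass balance %.2g)",
             field.max_at_window, field.mass_balance_error)
    table = None
    if convergence:
        table = grid_convergence(config.chamber)
        result["convergence"] = table
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"seed": config.seed, "config_hash": io.config_hash(config)}
        io.write_csv(field.to_frame(), out_dir / "concentration_field.csv", meta)
        with open(out_dir / "microenv_summary.txt", "w") as fh:
            fh.write(f"max_at_window_pM {field.max_at_window:.6g}\n")
            fh.write(f"mass_balance_error {field.mass_balance_error:.3g}\n")
        if table is not None:
            io.write_csv(table, out_dir / "grid_convergence.csv", meta)
    return result


def run_all(config: RunConfig, out_dir: Path) -> dict:
    """Full pipeline: simulate every AI level, quantify, analyze, transport."""
    out_dir = Path(out_dir)
    csvs = []
    for i, ai in enumerate(config.ai_levels_nM):
        run_dir = out_dir / f"run_ai{ai:g}"
        level_seed = int(substream(config.seed, 7, i).integers(0, 2**31 - 1))
        simulate_run(config, run_dir, ai_nM=ai, seed=level_seed)
        csvs.append(quantify_run(run_dir, config))
    results = analyze_run(csvs, config, out_dir / "analysis")
    results["microenv"] = run_microenv(config, out_dir / "microenv")
    return results
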
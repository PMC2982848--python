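"""Run configuration: one validated document with a block per pipeline stage.

Unknown keys are rejected on load so typos cannot silently fall back to
defaults. The master ``seed`` drives every random stream in the run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .microenv import ChamberSpec
from .synthetic import EnsembleModel, HillParams, ImagingModel

__all__ = [
    "PhotometryConfig", "TrajectoryConfig", "StatsConfig", "RunConfig", "load_config",
]

_DEFAULT_HILL = HillParams(k_eq=120.0, hill_n=2.7, i_max=38.0, i_base=2.0)


class PhotometryConfig(BaseModel):
    model_config = {"extra": "forbid"}

    min_length_px: float = 8.0
    max_length_px: float = 25.0
    k_sd: float = 6.0
    margin: int = 6
    displacement_tol_um: float = 0.6
    clip_residual: bool = False
    n_empty_rois: int = 8


class TrajectoryConfig(BaseModel):
    model_config = {"extra": "forbid"}

    filter_sd_min: float = 10.0
    final_window_min: float = 10.0
    dark_threshold: float = 15.0     # photons/min
    dark_at_min: float = 240.0


class StatsConfig(BaseModel):
    model_config = {"extra": "forbid"}

    level_t_min: float = 100.0       # per-cell averaging window (min)
    level_t_max: float = 250.0
    taus_min: list[float] = Field(default_factory=lambda: [10, 20, 30, 40, 60, 90])
    hill_weights: str | None = None  # None or "n_cells"


class RunConfig(BaseModel):
    model_config = {"extra": "forbid"}

    fixture: str | None = "MJ11-single"
    ensemble: EnsembleModel = Field(
        default_factory=lambda: EnsembleModel(hill=_DEFAULT_HILL, n_cells=30))
    imaging: ImagingModel = Field(default_factory=ImagingModel)
    photometry: PhotometryConfig = Field(default_factory=PhotometryConfig)
    trajectory: TrajectoryConfig = Field(default_factory=TrajectoryConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    chamber: ChamberSpec = Field(default_factory=ChamberSpec)
    ai_levels_nM: list[float] = Field(
        default_factory=lambda: [0, 30, 60, 100, 150, 250, 500, 1000])
    duration_min: float = 250.0
    seed: int = 0

    def ensemble_for(self, seed: int | None = None) -> EnsembleModel:
        """The ensemble model, from the named fixture when one is set."""
        from .fixtures import get_fixture

        s = self.seed if seed is None else seed
        if self.fixture and self.fixture != "stable-source":
            model = get_fixture(self.fixture, seed=s)
            return model.model_copy(update={"n_cells": self.ensemble.n_cells})
        return self.ensemble.model_copy(update={"seed": s})


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file; missing file or ``None`` gives defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig.model_validate(data)
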
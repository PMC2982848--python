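"""File formats: multi-page 16-bit TIFF stacks, metadata and result CSVs.

Every CSV written by the pipeline starts with ``#``-prefixed header lines
recording the software version, master seed and a hash of the run
configuration, so outputs are traceable; ``read_csv`` skips them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .photometry import Frame

METADATA_NAME = "frames.csv"
LEDGER_NAME = "ledger.csv"


def config_hash(config) -> str:
    """Short stable hash of a pydantic config object."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    lines = [f"# luxtrace_version: {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_csv(df: pd.DataFrame, path: Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta or {}))
        df.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_csv_meta(path: Path) -> dict:
    """The ``# key: value`` header of a pipeline CSV."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_stack(frames: list[np.ndarray], path: Path) -> None:
    """Write frames as one multi-page 16-bit TIFF (counts rounded/clipped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = [np.clip(np.round(f), 0, 65535).astype(np.uint16) for f in frames]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")


def read_stack(path: Path) -> list[np.ndarray]:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return [np.asarray(page, dtype=float) for page in data]


def write_run(
    out_dir: Path,
    dark_frames: list[np.ndarray],
    lum_frames: list[np.ndarray],
    times: np.ndarray,
    exposure: float,
    scene,
    meta: dict | None = None,
) -> None:
    """Write a simulated run: two TIFF stacks, frame metadata, truth ledger."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(dark_frames, out_dir / "darkfield.tif")
    write_stack(lum_frames, out_dir / "luminescence.tif")
    rows = []
    for j, t in enumerate(times):
        rows.append({"frame_index": j, "modality": "darkfield",
                     "t_start_min": float(t), "exposure_min": 0.1})
        rows.append({"frame_index": j, "modality": "luminescence",
                     "t_start_min": float(t), "exposure_min": exposure})
    write_csv(pd.DataFrame(rows), out_dir / METADATA_NAME, meta)
    led = [
        {"cell_id": c, "frame_index": j,
         "true_rate_photons_per_min": scene.true_rates[(c, j)],
         "true_photons": scene.ledger[(c, j)]}
        for (c, j) in sorted(scene.ledger)
    ]
    write_csv(pd.DataFrame(led, columns=["cell_id", "frame_index",
                                         "true_rate_photons_per_min", "true_photons"]),
              out_dir / LEDGER_NAME, meta)


def read_run(run_dir: Path) -> tuple[list[Frame], list[Frame], dict]:
    """Read a run directory back as (darkfield frames, luminescence frames, meta)."""
    run_dir = Path(run_dir)
    meta_path = run_dir / METADATA_NAME
    if not meta_path.exists():
        raise FileNotFoundError(f"missing frame metadata file: {meta_path}")
    table = read_csv(meta_path)
    meta = read_csv_meta(meta_path)
    dark_pages = read_stack(run_dir / "darkfield.tif")
    lum_pages = read_stack(run_dir / "luminescence.tif")
    dark, lum = [], []
    for _, row in table.iterrows():
        j = int(row["frame_index"])
        if row["modality"] == "darkfield":
            dark.append(Frame(dark_pages[j], "darkfield", float(row["exposure_min"]),
                              float(row["t_start_min"])))
        else:
            lum.append(Frame(lum_pages[j], "luminescence", float(row["exposure_min"]),
                             float(row["t_start_min"])))
    return dark, lum, meta
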
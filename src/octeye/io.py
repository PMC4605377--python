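"""File-format glue: multi-page TIFF stacks with CSV sidecars, biometry and
summary CSVs, seed files, and machine-readable run logs."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import OcteyeError
from .phantom import BScanImage

STACK_NAME = "stack.tif"
FRAMES_NAME = "frames.csv"
TRUTH_NAME = "truth.csv"
BIOMETRY_NAME = "biometry.csv"
SUMMARY_NAME = "summary.csv"


def write_stack(outdir: str | Path, frames: Sequence[BScanImage],
                truth: Optional[pd.DataFrame] = None) -> Path:
    """Write a time series as a multi-page TIFF plus sidecar metadata CSV
    (frame index, timestamp, phase, pitches) and optional ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = np.stack([f.data for f in frames]).astype(np.float32)
    tifffile.imwrite(outdir / STACK_NAME, data, photometric="minisblack")
    meta = pd.DataFrame({
        "frame": np.arange(len(frames)),
        "t_min": [f.timestamp for f in frames],
        "phase": [f.phase for f in frames],
        "axial_pitch_um": [f.axial_pitch for f in frames],
        "lateral_pitch_um": [f.lateral_pitch for f in frames],
    })
    meta.to_csv(outdir / FRAMES_NAME, index=False)
    if truth is not None:
        truth.to_csv(outdir / TRUTH_NAME, index=False)
    return outdir / STACK_NAME


def read_stack(indir: str | Path) -> list[BScanImage]:
    """Load a TIFF stack and its sidecar back into BScanImage frames."""
    indir = Path(indir)
    tif, meta_path = indir / STACK_NAME, indir / FRAMES_NAME
    if not tif.exists():
        raise OcteyeError(f"no image stack at {tif}")
    try:
        data = tifffile.imread(tif)
    except Exception as e:  # corrupt file: report which input failed
        raise OcteyeError(f"cannot read TIFF stack {tif}: {e}") from e
    if data.ndim == 2:
        data = data[None]
    if not meta_path.exists():
        raise OcteyeError(f"missing sidecar metadata {meta_path}")
    meta = pd.read_csv(meta_path)
    if len(meta) != len(data):
        raise OcteyeError(
            f"sidecar rows ({len(meta)}) do not match stack pages ({len(data)})")
    frames = []
    for i, row in meta.iterrows():
        try:
            frames.append(BScanImage(
                data=data[i], axial_pitch=float(row["axial_pitch_um"]),
                lateral_pitch=float(row["lateral_pitch_um"]),
                timestamp=float(row["t_min"]), phase=str(row["phase"])))
        except Exception as e:
            raise OcteyeError(f"frame {i} invalid: {e}") from e
    return frames


def read_seeds(path: str | Path) -> dict[str, tuple[float, float]]:
    """Seed points CSV with columns label, x_um, z_um."""
    df = pd.read_csv(path)
    required = {"label", "x_um", "z_um"}
    if not required <= set(df.columns):
        raise OcteyeError(f"seed file {path} must have columns {sorted(required)}")
    return {str(r["label"]): (float(r["x_um"]), float(r["z_um"]))
            for _, r in df.iterrows()}


def write_surfaces(path: str | Path, traces: dict[str, np.ndarray]) -> None:
    """Serialize surface traces as (label, x, z) rows."""
    rows = [(label, float(x), float(z))
            for label, arr in traces.items() for x, z in arr]
    pd.DataFrame(rows, columns=["label", "x_um", "z_um"]).to_csv(path, index=False)


def write_run_log(outdir: str | Path, stage: str, params: dict) -> Path:
    """Machine-readable log sufficient to reproduce a stage's outputs."""
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{stage}_log.json"
    payload = {
        "stage": stage,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "octeye_version": __version__,
        "python": platform.python_version(),
        "params": params,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
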
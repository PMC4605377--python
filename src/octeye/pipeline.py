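"""End-to-end measurement chain: segmentation → refraction correction →
biometry, for single frames and whole time series."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .biometry import BiometryRecord, measure_frame
from .errors import OcteyeError
from .phantom import BScanImage, TissueOptics
from .refraction import CorrectedSurfaceSet, dewarp
from .segmentation import SurfaceSet, detect_surfaces


def analyze_bscan(image: BScanImage, optics: Optional[TissueOptics] = None,
                  seeds: Optional[Mapping[str, tuple[float, float]]] = None,
                  lsi_fraction: float = 0.15,
                  ) -> tuple[BiometryRecord, SurfaceSet, CorrectedSurfaceSet]:
    """Measure one frame; returns the record plus both surface sets."""
    optics = optics or TissueOptics()
    raw = detect_surfaces(image, seeds=seeds)
    corrected = dewarp(raw, optics)
    record = measure_frame(image, raw, corrected, lsi_fraction=lsi_fraction)
    return record, raw, corrected


def analyze_stack(frames: Sequence[BScanImage],
                  optics: Optional[TissueOptics] = None,
                  seeds: Optional[Mapping[str, tuple[float, float]]] = None,
                  lsi_fraction: float = 0.15) -> pd.DataFrame:
    """Measure every frame of a time series into a biometry table."""
    rows = []
    for i, frame in enumerate(frames):
        try:
            rec, _, _ = analyze_bscan(frame, optics=optics, seeds=seeds,
                                      lsi_fraction=lsi_fraction)
        except OcteyeError as e:
            raise OcteyeError(f"frame {i} (t = {frame.timestamp} min): {e}") from e
        rows.append(rec.as_dict())
    return pd.DataFrame(rows)
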
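"""Optical-distortion correction by layer-by-layer Snell ray tracing.

OCT images depth in optical-path length, so every structure behind a
refractive interface appears displaced: too deep by the refractive index,
and laterally bent wherever the probing ray met a curved interface
obliquely.  This module converts segmented surface traces from image
(optical-path) coordinates to geometric coordinates: each interface is
fitted with a circular arc, and every A-scan ray is propagated anterior to
posterior — bent by Snell's law at each fitted arc, advanced by
(optical-path increment) / n through each layer.

On the AP axis (normal incidence) the correction reduces exactly to
thickness / n per layer, which :func:`axial_correct` exposes directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import GeometryError, MeasurementError
from .phantom import TissueOptics, refract
from .segmentation import AXIAL_LABELS, IRIS_LABELS, SurfaceSet


@dataclass(frozen=True)
class ArcModel:
    """Fitted circular-arc interface (geometric coordinates, μm).

    ``branch`` selects which half of the circle the surface lies on:
    −1 → z = cz − √(R² − dx²) (surface anterior to its centre, e.g. cornea),
    +1 → the posterior half.  ``radius`` is infinite for a flat model.
    """

    cx: float
    cz: float
    radius: float
    branch: int = -1
    z0: float = 0.0          # flat-model depth
    rms: float = 0.0
    n_points: int = 0

    @property
    def is_flat(self) -> bool:
        return not math.isfinite(self.radius)

    @property
    def signed_radius(self) -> float:
        """> 0 when the centre of curvature lies posterior to the surface."""
        if self.is_flat:
            return math.inf
        return self.radius if self.branch < 0 else -self.radius

    def z_eval(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.is_flat:
            return np.full_like(np.asarray(x, dtype=float), self.z0) \
                if np.ndim(x) else self.z0
        dx = np.asarray(x, dtype=float) - self.cx
        z = self.cz + self.branch * np.sqrt(np.clip(self.radius ** 2 - dx ** 2, 0, None))
        return z if np.ndim(x) else float(z)

    def normal_at(self, p: np.ndarray) -> np.ndarray:
        if self.is_flat:
            return np.array([0.0, -1.0])
        v = p - np.array([self.cx, self.cz])
        n = np.linalg.norm(v)
        if n == 0:
            return np.array([0.0, -1.0])
        return v / n


def fit_interface(points: np.ndarray | Iterable, max_radius: float = 5.0e5,
                  mad_factor: float = 3.0) -> ArcModel:
    """Fit a circular arc (algebraic least squares) with robust re-fitting.

    Points farther than ``mad_factor`` median absolute deviations from the
    first fit are rejected once and the arc re-fitted.  Collinear points, or
    a radius beyond ``max_radius``, fall back to a flat model rather than
    failing.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise MeasurementError("arc fit needs at least 3 points")

    def kasa(p: np.ndarray) -> Optional[tuple[float, float, float]]:
        A = np.column_stack([p[:, 0], p[:, 1], np.ones(len(p))])
        bvec = p[:, 0] ** 2 + p[:, 1] ** 2
        sol, _, rank, _ = np.linalg.lstsq(A, bvec, rcond=None)
        if rank < 3:
            return None
        cx, cz = sol[0] / 2, sol[1] / 2
        r2 = sol[2] + cx ** 2 + cz ** 2
        if r2 <= 0:
            return None
        return cx, cz, math.sqrt(r2)

    def flat(p: np.ndarray) -> ArcModel:
        z0 = float(np.mean(p[:, 1]))
        return ArcModel(cx=float(np.mean(p[:, 0])), cz=z0, radius=math.inf, z0=z0,
                        rms=float(np.sqrt(np.mean((p[:, 1] - z0) ** 2))),
                        n_points=len(p))

    fit = kasa(pts)
    if fit is not None and len(pts) > 4:
        cx, cz, r = fit
        res = np.abs(np.hypot(pts[:, 0] - cx, pts[:, 1] - cz) - r)
        mad = np.median(np.abs(res - np.median(res)))
        keep = res <= np.median(res) + mad_factor * max(mad, 1e-9)
        if keep.sum() >= 3 and keep.sum() < len(pts):
            pts = pts[keep]
            fit = kasa(pts) or fit
    if fit is None:
        return flat(pts)
    cx, cz, r = fit
    if r > max_radius:
        return flat(pts)
    res = np.hypot(pts[:, 0] - cx, pts[:, 1] - cz) - r
    branch = -1 if float(np.median(pts[:, 1])) < cz else 1
    return ArcModel(cx=float(cx), cz=float(cz), radius=float(r), branch=branch,
                    rms=float(np.sqrt(np.mean(res ** 2))), n_points=len(pts))


@dataclass
class CorrectedSurfaceSet:
    """Surface traces in geometric coordinates after Snell dewarping."""

    traces: dict[str, np.ndarray]          # label -> (N, 2) geometric (x, z) μm
    arcs: dict[str, ArcModel]              # fitted interface models
    indices: dict[str, float]              # index of the medium behind each interface
    axis_x: float = 0.0
    vertex: Optional[tuple[float, float]] = None
    excluded: dict[str, int] = field(default_factory=dict)   # label -> points dropped
    pupil_halfwidth: Optional[float] = None

    def has(self, label: str) -> bool:
        return label in self.traces and len(self.traces[label]) >= 2

    def z_at(self, label: str, x: float) -> float:
        """Surface depth at lateral position x, from the fitted arc when
        available (robust to per-point noise), else interpolated."""
        if label in self.arcs:
            return float(self.arcs[label].z_eval(x))
        tr = self.traces[label]
        return float(np.interp(x, tr[:, 0], tr[:, 1]))


#: Refractive index of the medium *anterior* to each interface (air = 1).
def _index_before(optics: TissueOptics) -> dict[str, float]:
    return {"cornea_anterior": 1.0, "cornea_posterior": optics.n_cornea,
            "lens_anterior": optics.n_aqueous, "lens_posterior": optics.n_lens,
            "ilm": optics.n_vitreous}


def dewarp(surfaces: SurfaceSet, optics: TissueOptics,
           pupil_margin: float = 0.95) -> CorrectedSurfaceSet:
    """Correct all surface traces from optical-path to geometric coordinates.

    Proceeds anterior → posterior: each surface is corrected through the
    arcs fitted to the already-corrected shallower surfaces, then fitted
    itself.  Rays suffering total internal reflection, or leaving the span
    of a shallower trace, are excluded (counted, never silent).  With the
    iris present, lens and retinal points outside ``pupil_margin`` × the
    pupil half-width are excluded from the arc fits as unreliable.
    """
    order = [l for l in AXIAL_LABELS if surfaces.has(l)]
    if not order or order[0] != "cornea_anterior":
        raise MeasurementError("dewarp requires the corneal anterior trace")
    n_before = _index_before(optics)
    axis_x = surfaces.axis_x if surfaces.axis_x is not None else 0.0

    # pupil half-width from the innermost iris pigment-epithelium points
    # (a low quantile of each wing's |x|, robust to stray points)
    pupil_hw = None
    inner = [float(np.percentile(np.abs(surfaces.traces[l][:, 0] - axis_x), 5))
             for l in IRIS_LABELS if surfaces.has(l)]
    if inner:
        pupil_hw = max(min(inner), 10 * surfaces.lateral_pitch)

    arcs: dict[str, ArcModel] = {}
    corrected: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}

    def correct_trace(target: np.ndarray, path: list[str], n_last: float
                      ) -> tuple[np.ndarray, np.ndarray, int]:
        """Trace every (x, z_optical) of ``target`` through ``path``.

        Besides the corrected points, returns each ray's lateral position at
        the anterior lens plane (the iris aperture) — the criterion for
        whether a deep point saw the pupil or the iris."""
        out, aper, dropped = [], [], 0
        for x, z in target:
            p = np.array([x, 0.0])
            d = np.array([0.0, 1.0])
            opl, ok = 0.0, True
            x_aperture = math.nan
            for j, lab in enumerate(path):
                tr = surfaces.traces[lab]
                if not (tr[0, 0] - 1e-6 <= x <= tr[-1, 0] + 1e-6):
                    ok = False
                    break
                zj = float(surfaces.z_at(lab, x))
                if zj < opl - 1e-6:
                    ok = False
                    break
                p = p + d * ((zj - opl) / n_before[lab])
                opl = zj
                if lab == "lens_anterior":
                    x_aperture = p[0]
                n_next = n_before[path[j + 1]] if j + 1 < len(path) else n_last
                d_new = refract(d, arcs[lab].normal_at(p), n_before[lab], n_next)
                if d_new is None:          # total internal reflection
                    ok = False
                    break
                d = d_new
            if ok and z >= opl - 1e-6:
                q = p + d * ((z - opl) / n_last)
                out.append((q[0], q[1]))
                aper.append(q[0] if math.isnan(x_aperture) else x_aperture)
            else:
                dropped += 1
        arr = np.asarray(out, dtype=float).reshape(-1, 2)
        ap = np.asarray(aper, dtype=float)
        ordx = np.argsort(arr[:, 0]) if len(arr) else np.array([], dtype=int)
        return arr[ordx], ap[ordx], dropped

    for k, label in enumerate(order):
        if k == 0:
            # air: optical and geometric coordinates coincide
            arr, ap, dropped = surfaces.traces[label].copy(), \
                surfaces.traces[label][:, 0].copy(), 0
        else:
            arr, ap, dropped = correct_trace(surfaces.traces[label], order[:k],
                                             n_before[label])
        corrected[label] = arr
        excluded[label] = dropped
        fit_pts = arr
        if pupil_hw is not None and label in ("lens_anterior", "lens_posterior", "ilm"):
            mask = np.abs(ap - axis_x) <= pupil_margin * pupil_hw
            if mask.sum() >= 3:
                fit_pts = arr[mask]
        if len(fit_pts) >= 3:
            arcs[label] = fit_interface(fit_pts)

    # iris pigment epithelium: inside the aqueous, no refraction of its own
    for label in IRIS_LABELS:
        if surfaces.has(label):
            path = [l for l in ("cornea_anterior", "cornea_posterior") if l in arcs]
            arr, _, dropped = correct_trace(surfaces.traces[label], path,
                                            optics.n_aqueous)
            corrected[label] = arr
            excluded[label] = dropped

    vertex = None
    if surfaces.vertex is not None:
        vertex = (float(surfaces.vertex[0]), float(surfaces.vertex[1]))
    return CorrectedSurfaceSet(traces=corrected, arcs=arcs,
                               indices=dict(optics.index_stack()),
                               axis_x=axis_x, vertex=vertex,
                               excluded=excluded, pupil_halfwidth=pupil_hw)


def axial_correct(optical_thickness: float, n: float) -> float:
    """Geometric thickness of a layer from its optical thickness: t / n."""
    if n < 1.0:
        raise GeometryError(f"refractive index must be ≥ 1, got {n}")
    if optical_thickness < 0:
        raise GeometryError("optical thickness must be non-negative")
    return optical_thickness / n


def drop_index_spread(indices: Iterable[float] | None = None) -> float:
    """Maximum pairwise relative difference (fraction, relative to the
    larger index) among the stress-agent refractive indices.

    The spread of the NaCl-drop indices is small enough that a single index
    choice changes any corrected thickness by well under 1 %.
    """
    vals = list(indices) if indices is not None else \
        list(TissueOptics().drop_indices.values())
    return max(abs(a - b) / max(a, b) for a in vals for b in vals)
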
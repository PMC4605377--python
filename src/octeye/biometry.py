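"""The six biometric parameters.

Axial distances (CCT, ACD, LT, CRD) are evaluated along the AP axis on the
refraction-corrected surfaces.  LSI is the mean linear backscatter of the
anterior lens sampled on the *uncorrected* image, since the average runs
along the A-scan.  IC is the signed maximum perpendicular distance of each
iris pigment-epithelium wing from its root→contact chord, positive toward
the cornea (anterior / convex bowing), averaged over the two wings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .errors import MeasurementError
from .phantom import BScanImage
from .refraction import CorrectedSurfaceSet
from .segmentation import SurfaceSet

PARAMS = ("CCT", "ACD", "LT", "CRD", "LSI", "IC")


@dataclass
class BiometryRecord:
    """All six parameters at one timestamp (distances μm, LSI linear a.u.,
    IC signed μm, + = anterior bowing)."""

    CCT: float = math.nan
    ACD: float = math.nan
    LT: float = math.nan
    CRD: float = math.nan
    LSI: float = math.nan
    IC: float = math.nan
    timestamp: float = 0.0
    phase: str = ""
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"t_min": self.timestamp, "phase": self.phase,
                **{p: getattr(self, p) for p in PARAMS},
                "flags": ";".join(self.flags)}

    def validate(self) -> "BiometryRecord":
        for name in ("CCT", "ACD", "LT", "CRD"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise MeasurementError(f"{name} must be positive, got {v:.2f} μm")
        if all(not math.isnan(getattr(self, n)) for n in ("ACD", "LT", "CRD")) \
                and self.CRD <= self.ACD + self.LT:
            raise MeasurementError("CRD must exceed ACD + LT (vitreous depth > 0)")
        if not math.isnan(self.LSI) and self.LSI < 0:
            raise MeasurementError("LSI must be non-negative")
        return self


def measure_axial(surfaces: CorrectedSurfaceSet) -> dict[str, float]:
    """CCT, ACD, LT, CRD at the AP-axis lateral position (geometric μm).

    Surfaces are evaluated from their fitted arc models at the axis;
    a missing surface fails only the parameters that need it.
    """
    x = surfaces.axis_x
    z = {}
    for label in ("cornea_anterior", "cornea_posterior", "lens_anterior",
                  "lens_posterior", "ilm"):
        if surfaces.has(label):
            z[label] = surfaces.z_at(label, x)

    def dist(a: str, b: str, name: str) -> float:
        if a not in z or b not in z:
            return math.nan
        d = z[b] - z[a]
        if d <= 0:
            raise MeasurementError(f"degenerate {name}: non-positive thickness {d:.2f} μm")
        return d

    return {"CCT": dist("cornea_anterior", "cornea_posterior", "CCT"),
            "ACD": dist("cornea_posterior", "lens_anterior", "ACD"),
            "LT": dist("lens_anterior", "lens_posterior", "LT"),
            "CRD": dist("cornea_posterior", "ilm", "CRD")}


def measure_lsi(image: BScanImage, surfaces: SurfaceSet,
                region_fraction: float = 0.15,
                lateral_halfwidth: int = 8) -> float:
    """Mean linear backscatter of the anterior lens.

    Samples the raw image along the AP-axis A-scan from the anterior lens
    boundary down to ``region_fraction`` of the (optical) lens thickness —
    the anterior-capsule-to-anterior-nucleus span — averaged over a small
    lateral band to tame speckle.
    """
    if not (0.0 < region_fraction <= 1.0):
        raise MeasurementError("LSI region fraction must lie in (0, 1]")
    for lab in ("lens_anterior", "lens_posterior"):
        if not surfaces.has(lab):
            raise MeasurementError(f"LSI needs the {lab} trace")
    axis_x = surfaces.axis_x if surfaces.axis_x is not None else 0.0
    z0 = float(surfaces.z_at("lens_anterior", axis_x))
    z1 = float(surfaces.z_at("lens_posterior", axis_x))
    r0 = z0 / image.axial_pitch
    r1 = (z0 + region_fraction * (z1 - z0)) / image.axial_pitch
    # keep clear of the capsule edge itself
    lo, hi = int(math.ceil(r0)) + 2, int(math.floor(r1)) - 1
    ncols = image.data.shape[1]
    j0 = int(round(axis_x / image.lateral_pitch + (ncols - 1) / 2))
    jlo, jhi = max(0, j0 - lateral_halfwidth), min(ncols, j0 + lateral_halfwidth + 1)
    if hi < lo or jhi <= jlo or hi >= image.data.shape[0]:
        raise MeasurementError("empty LSI sampling window")
    return float(np.mean(image.data[lo:hi + 1, jlo:jhi]))


def _chord_deviation(xs: np.ndarray, zs: np.ndarray, root: np.ndarray,
                     contact: np.ndarray) -> float:
    """Signed max perpendicular distance of the curve (xs, zs) from the
    root→contact chord; + toward the cornea (smaller z).

    The per-point distances are median-smoothed over 5 lateral neighbours
    before taking the extreme, so a single noisy point cannot set the IC.
    """
    chord = contact - root
    norm = np.linalg.norm(chord)
    if norm < 1e-9:
        raise MeasurementError("iris wing degenerate: root equals contact")
    nhat = np.array([-chord[1], chord[0]]) / norm
    if nhat[1] > 0:                       # orient toward the cornea
        nhat = -nhat
    d = (np.column_stack([xs, zs]) - root) @ nhat
    if d.size >= 11:
        # local-quadratic smoothing: unbiased for smoothly curved wings,
        # suppresses the max-statistic noise of single points
        win = min(15, d.size if d.size % 2 else d.size - 1)
        d = savgol_filter(d, window_length=win, polyorder=2, mode="interp")
    elif d.size >= 7:
        d = median_filter(d, size=5, mode="nearest")
    return float(d[np.argmax(np.abs(d))])


def _wing_ic(points: np.ndarray, axis_x: float, surfaces: CorrectedSurfaceSet
             ) -> tuple[float, bool]:
    """Signed IC of one wing.

    The pigment-epithelium trace is fitted with a quadratic in x (the wing
    shape model) so the landmarks are robust to per-point noise.  The root
    is the most peripheral trace point; the contact point is where the
    fitted wing meets the anterior lens arc — detection clips the trace
    just short of the contact, so the fit is extrapolated toward the axis.
    Falls back to the iris tip (innermost trace point) when no intersection
    with the lens is found.
    """
    if len(points) >= 11:
        # denoise the trace first: local-quadratic smoothing is exact for
        # the parabolic wing shapes the fit below assumes
        win = min(17, len(points) if len(points) % 2 else len(points) - 1)
        points = np.column_stack([
            points[:, 0],
            savgol_filter(points[:, 1], window_length=win, polyorder=2,
                          mode="interp")])
    lat = np.abs(points[:, 0] - axis_x)
    root = points[np.argmax(lat)].copy()
    tip = points[np.argmin(lat)].copy()
    if len(points) >= 5:
        # boundary detection is biased where the iris band fades out; fit on
        # the interior and extrapolate to the landmark positions
        fit_pts = points
        if len(points) >= 15:
            order = np.argsort(lat)
            fit_pts = points[np.sort(order[3:-3])]
        coeff = np.polyfit(fit_pts[:, 0], fit_pts[:, 1], 2)
        wing_z = lambda x: np.polyval(coeff, x)
        root[1] = wing_z(root[0])
        tip[1] = wing_z(tip[0])
    else:
        order = np.argsort(points[:, 0])
        wing_z = lambda x: np.interp(x, points[order, 0], points[order, 1])

    def surface_crossing(start: np.ndarray, outward: bool, label: str,
                         reach: float) -> Optional[np.ndarray]:
        """Where the fitted wing, walked from ``start``, meets a surface."""
        side = 1.0 if start[0] >= axis_x else -1.0
        step = side if outward else -side
        xs = start[0] + step * np.linspace(0.0, reach, 200)
        gap = np.asarray([wing_z(x) - surfaces.z_at(label, float(x)) for x in xs])
        if abs(gap[0]) < 5.0:
            return np.array([start[0], float(wing_z(start[0]))])
        sign0 = np.sign(gap[0]) or 1.0
        cross = np.flatnonzero(np.sign(gap) != sign0)
        if not cross.size:
            return None
        i = cross[0]
        frac = gap[i - 1] / (gap[i - 1] - gap[i])
        x_c = float(xs[i - 1] + frac * (xs[i] - xs[i - 1]))
        return np.array([x_c, float(wing_z(x_c))])

    span = abs(root[0] - tip[0])
    contact, fallback = tip, True
    if surfaces.has("lens_anterior") and len(points) >= 5:
        hit = surface_crossing(tip, outward=False, label="lens_anterior",
                               reach=0.6 * abs(tip[0] - axis_x))
        if hit is not None:
            contact, fallback = hit, False
    # the root inserts at the iridocorneal angle: extrapolate the wing to
    # its crossing with the corneal endothelium when one exists nearby
    if surfaces.has("cornea_posterior") and len(points) >= 5:
        hit = surface_crossing(root, outward=True, label="cornea_posterior",
                               reach=0.35 * span)
        if hit is not None:
            root = hit

    # deviation evaluated on the measured points themselves (the fit only
    # supplies the landmarks), so non-parabolic wings are measured as-is
    return _chord_deviation(points[:, 0], points[:, 1], root, contact), fallback


def measure_ic(surfaces: CorrectedSurfaceSet) -> tuple[float, list[str]]:
    """Iris curvature, mean of the two wings (μm, + = anterior bowing).

    If a wing never meets the anterior lens surface (no detectable
    iris–lens contact), the iris tip serves as the central landmark and the
    record is flagged.
    """
    wings, flags = [], []
    for label in ("iris_ipe_left", "iris_ipe_right"):
        if not surfaces.has(label):
            continue
        ic, fallback = _wing_ic(surfaces.traces[label], surfaces.axis_x, surfaces)
        if fallback:
            flags.append(f"{label}:no_contact")
        wings.append(ic)
    if not wings:
        raise MeasurementError("no iris pigment-epithelium trace for IC")
    return float(np.mean(wings)), flags


def measure_frame(image: BScanImage, raw: SurfaceSet,
                  corrected: CorrectedSurfaceSet,
                  lsi_fraction: float = 0.15) -> BiometryRecord:
    """Assemble the full record for one frame; parameters whose surfaces are
    unavailable come back NaN with a flag rather than aborting the frame."""
    rec = BiometryRecord(timestamp=image.timestamp, phase=image.phase)
    axial = measure_axial(corrected)
    for k, v in axial.items():
        setattr(rec, k, v)
        if math.isnan(v):
            rec.flags.append(f"{k}:missing_surface")
    try:
        rec.LSI = measure_lsi(image, raw, region_fraction=lsi_fraction)
    except MeasurementError as e:
        rec.flags.append(f"LSI:{e}")
    try:
        rec.IC, ic_flags = measure_ic(corrected)
        rec.flags.extend(ic_flags)
    except MeasurementError as e:
        rec.flags.append(f"IC:{e}")
    return rec.validate()
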
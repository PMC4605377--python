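"""Synthetic full-eye OCT phantom.

Generates ground-truthed B-scans of a schematic eye (cornea, anterior
chamber, iris, crystalline lens, retina) under osmotic challenge.  The
forward model traces one probing ray per A-scan from anterior to posterior:
at every curved interface the ray bends according to Snell's law (surface
normals from circular-arc interfaces), and backscatter is deposited at the
*accumulated optical path* depth (geometric segment length times the local
refractive index) — exactly the distortion a real OCT image carries and the
refraction module later undoes.

Axial image coordinates are therefore optical-path length in air; all
geometry is in micrometres.  Depth increases posteriorly, lateral 0 is the
image centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ScheduleError, TruncationError
from .scenario import RESPONSE_PARAMS, OsmoticScenario

_DOWN = np.array([0.0, 1.0])


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArcSurface:
    """Circular-arc interface: apex position plus signed radius.

    ``radius`` > 0 means the centre of curvature lies posterior to the apex
    (surface convex toward the anterior, e.g. the cornea); ``radius`` < 0 the
    opposite (e.g. the posterior lens capsule); ``inf`` is flat.  The arc is
    only defined within ``half_width`` of its apex laterally.
    """

    apex_z: float
    radius: float
    half_width: float
    apex_x: float = 0.0

    @property
    def is_flat(self) -> bool:
        return not math.isfinite(self.radius)

    @property
    def center(self) -> tuple[float, float]:
        return (self.apex_x, self.apex_z + self.radius)

    def z_at(self, x: np.ndarray | float) -> np.ndarray | float:
        """Axial position of the surface at lateral position(s) ``x``."""
        if self.is_flat:
            return np.full_like(np.asarray(x, dtype=float), self.apex_z) \
                if np.ndim(x) else self.apex_z
        dx = np.asarray(x, dtype=float) - self.apex_x
        s = np.sqrt(self.radius ** 2 - dx ** 2)
        z = (self.apex_z + self.radius) - np.sign(self.radius) * s
        return z if np.ndim(x) else float(z)

    def normal_at(self, p: np.ndarray) -> np.ndarray:
        """Unit normal at surface point ``p``, pointing anterior (−z side)."""
        if self.is_flat:
            return np.array([0.0, -1.0])
        c = np.asarray(self.center)
        v = p - c
        v = v / np.linalg.norm(v)
        return v if v[1] < 0 else -v


@dataclass(frozen=True)
class IrisWing:
    """One iris wing modelled by its pigment-epithelium curve: a quadratic
    through the root, the mid-span sag apex, and the iris–lens contact point.

    ``sag`` is the perpendicular offset of the apex from the root→contact
    chord, signed positive toward the cornea (anterior bowing)."""

    root: tuple[float, float]      # (x, z) μm — peripheral attachment
    contact: tuple[float, float]   # (x, z) μm — iris–lens contact point
    sag: float                     # μm, + = anterior bowing

    def coefficients(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bezier-style coefficients: P(u) = A + B·u + C·u², u ∈ [0, 1]."""
        r = np.asarray(self.root, dtype=float)
        k = np.asarray(self.contact, dtype=float)
        t = k - r
        nhat = np.array([-t[1], t[0]])
        nhat /= np.linalg.norm(nhat)
        if nhat[1] > 0:           # ensure anterior (−z) orientation
            nhat = -nhat
        return r, t + 4.0 * self.sag * nhat, -4.0 * self.sag * nhat

    def point(self, u: np.ndarray | float) -> np.ndarray:
        a, b, c = self.coefficients()
        u = np.asarray(u, dtype=float)
        return a + np.multiply.outer(u, b) + np.multiply.outer(u ** 2, c)


@dataclass(frozen=True)
class EyeGeometry:
    """Ground-truth geometry of all ocular surfaces at one instant (μm)."""

    cornea_anterior: ArcSurface
    cornea_posterior: ArcSurface
    lens_anterior: ArcSurface
    lens_posterior: ArcSurface
    ilm: ArcSurface
    iris: Optional[tuple[IrisWing, IrisWing]] = None   # (left, right)
    iris_thickness: float = 40.0
    pupil_radius: float = 500.0
    lateral_extent: float = 1040.0
    axis_x: float = 0.0
    retina_thickness: float = 150.0

    # -- derived axial biometry (all along the AP axis, apex-to-apex) ------
    @property
    def cct(self) -> float:
        return self.cornea_posterior.apex_z - self.cornea_anterior.apex_z

    @property
    def acd(self) -> float:
        return self.lens_anterior.apex_z - self.cornea_posterior.apex_z

    @property
    def lt(self) -> float:
        return self.lens_posterior.apex_z - self.lens_anterior.apex_z

    @property
    def crd(self) -> float:
        return self.ilm.apex_z - self.cornea_posterior.apex_z

    @property
    def iris_sag(self) -> float:
        return self.iris[1].sag if self.iris is not None else float("nan")

    def surfaces(self) -> dict[str, ArcSurface]:
        return {
            "cornea_anterior": self.cornea_anterior,
            "cornea_posterior": self.cornea_posterior,
            "lens_anterior": self.lens_anterior,
            "lens_posterior": self.lens_posterior,
            "ilm": self.ilm,
        }

    def validate(self) -> "EyeGeometry":
        apexes = [s.apex_z for s in self.surfaces().values()]
        if not all(a < b for a, b in zip(apexes, apexes[1:])):
            raise GeometryError(f"surface apexes not AP-ordered: {apexes}")
        for name, v in (("CCT", self.cct), ("ACD", self.acd), ("LT", self.lt),
                        ("CRD", self.crd), ("vitreous depth", self.crd - self.acd - self.lt)):
            if v <= 0:
                raise GeometryError(f"{name} must be positive, got {v:.1f} μm")
        # surfaces must not cross anywhere on their shared lateral support
        items = list(self.surfaces().items())
        for (na, sa), (nb, sb) in zip(items, items[1:]):
            w = min(sa.half_width, sb.half_width, self.lateral_extent)
            xs = self.axis_x + np.linspace(-w, w, 41)
            if not np.all(sa.z_at(xs) < sb.z_at(xs)):
                raise GeometryError(f"surfaces {na} and {nb} cross laterally")
        if self.iris is not None:
            for wing in self.iris:
                if abs(wing.root[0] - self.axis_x) <= abs(wing.contact[0] - self.axis_x):
                    raise GeometryError("iris root must be lateral to the lens-contact point")
        if self.pupil_radius <= 0:
            raise GeometryError("pupil radius must be positive")
        return self

    def at_meridian(self, y_offset: float) -> "EyeGeometry":
        """Cross-section of the (assumed rotationally symmetric) eye at a
        vertical offset from the vertex meridian: every spherical surface
        appears with reduced radius and shifted apex."""
        def slice_arc(s: ArcSurface) -> ArcSurface:
            if s.is_flat:
                return s
            if abs(y_offset) >= abs(s.radius):
                raise GeometryError("meridian offset exceeds surface radius")
            r2 = math.copysign(math.sqrt(s.radius ** 2 - y_offset ** 2), s.radius)
            cz = s.apex_z + s.radius
            return replace(s, radius=r2, apex_z=cz - r2)
        return replace(
            self,
            cornea_anterior=slice_arc(self.cornea_anterior),
            cornea_posterior=slice_arc(self.cornea_posterior),
            lens_anterior=slice_arc(self.lens_anterior),
            lens_posterior=slice_arc(self.lens_posterior),
            ilm=slice_arc(self.ilm),
        )


@dataclass(frozen=True)
class LayerIntensities:
    """Mean linear backscatter per medium (arbitrary units)."""

    background: float = 0.01
    cornea: float = 0.45
    aqueous: float = 0.12
    lens: float = 0.35
    vitreous: float = 0.08
    retina: float = 0.75
    iris: float = 1.00

    def get(self, medium: str) -> float:
        return getattr(self, medium)


@dataclass(frozen=True)
class TissueOptics:
    """Refractive indices and scattering parameters of the ocular media.

    Index defaults follow the standard full-eye stack (cornea 1.40, aqueous
    1.33, crystalline lens 1.57, vitreous 1.33); the measured indices of the
    NaCl stress agents are keyed by osmolality and differ by < 0.82 %, so
    tissue indices are treated as hydration-independent.
    """

    n_cornea: float = 1.40
    n_aqueous: float = 1.33
    n_lens: float = 1.57
    n_vitreous: float = 1.33
    n_retina: float = 1.38
    drop_indices: dict[float, float] = field(
        default_factory=lambda: {1000.0: 1.344, 500.0: 1.342, 250.0: 1.337, 100.0: 1.333})
    intensities: LayerIntensities = field(default_factory=LayerIntensities)
    lens_multiplier: float = 1.0          # opacified / baseline intensity ratio
    lens_front_fraction: float = 0.30     # opacification front depth, fraction of LT
    lens_front_width: float = 60.0        # μm optical, smoothness of the front

    def __post_init__(self):
        for name in ("n_cornea", "n_aqueous", "n_lens", "n_vitreous", "n_retina"):
            if getattr(self, name) < 1.0:
                raise GeometryError(f"refractive index {name} must be ≥ 1")
        if any(v < 1.0 for v in self.drop_indices.values()):
            raise GeometryError("drop indices must be ≥ 1")
        if not (0.0 <= self.lens_front_fraction <= 1.0):
            raise GeometryError("lens front fraction must lie in [0, 1]")

    def index_stack(self) -> dict[str, float]:
        """Refractive index of the medium *posterior* to each interface."""
        return {
            "cornea_anterior": self.n_cornea,
            "cornea_posterior": self.n_aqueous,
            "lens_anterior": self.n_lens,
            "lens_posterior": self.n_vitreous,
            "ilm": self.n_retina,
        }


@dataclass(frozen=True)
class ImagingConfig:
    """Sampling of the B-scan: pitches in μm/pixel, array shape."""

    axial_pitch: float = 3.0     # μm of optical path per pixel
    lateral_pitch: float = 10.0  # μm per A-scan
    n_rows: int = 1728
    n_cols: int = 192

    def __post_init__(self):
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise GeometryError("pixel pitches must be positive")

    @property
    def depth(self) -> float:
        return self.n_rows * self.axial_pitch

    def x_coords(self) -> np.ndarray:
        return (np.arange(self.n_cols) - (self.n_cols - 1) / 2) * self.lateral_pitch


@dataclass
class BScanImage:
    """2D OCT intensity image; rows are axial optical-path depth."""

    data: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    timestamp: float = 0.0
    phase: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise GeometryError("pixel pitches must be positive")
        if np.any(self.data < 0):
            raise GeometryError("OCT intensities must be non-negative")

    def x_coords(self) -> np.ndarray:
        n = self.data.shape[1]
        return (np.arange(n) - (n - 1) / 2) * self.lateral_pitch


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative speckle plus additive detector noise.

    Speckle is unit-mean gamma with ``looks`` incoherent averages (contrast
    1/√looks; looks = 1 is fully developed exponential speckle)."""

    speckle_looks: float = 8.0
    additive_sigma: float = 0.01


# ---------------------------------------------------------------------------
# default eyes
# ---------------------------------------------------------------------------

def mouse_geometry(axis_x: float = 0.0, cct: float = 119.0, acd: float = 404.0,
                   lt: float = 1860.0, crd: float = 3080.0,
                   iris_sag: float = 28.6) -> EyeGeometry:
    """Schematic adult-mouse eye at its pre-challenge baseline.

    Axial distances are the in-vivo baselines (CCT 119, ACD 404, LT 1860,
    CRD 3080 μm); curvature radii are plausible defaults for the mouse eye
    (they are free configuration, not measured values).
    """
    z0 = 150.0  # air gap above the corneal apex
    la_z = z0 + cct + acd
    lens_ant = ArcSurface(la_z, 1000.0, 900.0, axis_x)
    cornea_post = ArcSurface(z0 + cct, 1450.0, 1200.0, axis_x)
    # iris root inserts at the iridocorneal angle (on the posterior cornea);
    # the contact point sits on the anterior lens at the pupil margin
    pupil_r, root_lat = 500.0, 950.0
    wings = tuple(
        IrisWing(
            root=(axis_x + side * root_lat, float(cornea_post.z_at(axis_x + side * root_lat))),
            contact=(axis_x + side * pupil_r, float(lens_ant.z_at(axis_x + side * pupil_r))),
            sag=iris_sag,
        )
        for side in (-1, 1)
    )
    return EyeGeometry(
        cornea_anterior=ArcSurface(z0, 1500.0, 1200.0, axis_x),
        cornea_posterior=cornea_post,
        lens_anterior=lens_ant,
        lens_posterior=ArcSurface(la_z + lt, -1000.0, 900.0, axis_x),
        ilm=ArcSurface(z0 + cct + crd, -1700.0, 2000.0, axis_x),
        iris=wings,  # type: ignore[arg-type]
        pupil_radius=pupil_r,
        lateral_extent=1040.0,
        axis_x=axis_x,
    ).validate()


def model_eye_geometry(axis_x: float = 0.0) -> EyeGeometry:
    """Schematic OCT calibration model eye: manufacturer anterior-segment
    dimensions CCT 0.55 mm, ACD 3.03 mm, LT 3.9 mm, plus a 2.0 mm synthetic
    vitreous depth so the full pipeline (which requires a retina) runs."""
    z0, cct, acd, lt, vit = 200.0, 550.0, 3030.0, 3900.0, 2000.0
    return EyeGeometry(
        cornea_anterior=ArcSurface(z0, 7800.0, 3000.0, axis_x),
        cornea_posterior=ArcSurface(z0 + cct, 6800.0, 3000.0, axis_x),
        lens_anterior=ArcSurface(z0 + cct + acd, 10000.0, 3000.0, axis_x),
        lens_posterior=ArcSurface(z0 + cct + acd + lt, -6000.0, 3000.0, axis_x),
        ilm=ArcSurface(z0 + cct + acd + lt + vit, -11000.0, 3000.0, axis_x),
        iris=None,
        pupil_radius=1500.0,
        lateral_extent=2400.0,
        axis_x=axis_x,
    ).validate()


def mouse_optics() -> TissueOptics:
    return TissueOptics()


def model_eye_optics() -> TissueOptics:
    return TissueOptics()


def default_imaging(preset: str = "mouse", **overrides) -> ImagingConfig:
    base = dict(axial_pitch=3.0, lateral_pitch=10.0, n_rows=1728, n_cols=208)
    if preset == "model_eye":
        base = dict(axial_pitch=6.0, lateral_pitch=25.0, n_rows=2400, n_cols=192)
    base.update(overrides)
    return ImagingConfig(**base)


def baseline_for(preset: str) -> tuple[EyeGeometry, TissueOptics]:
    if preset == "model_eye":
        return model_eye_geometry(), model_eye_optics()
    return mouse_geometry(), mouse_optics()


# ---------------------------------------------------------------------------
# osmotic response
# ---------------------------------------------------------------------------

def osmotic_response(baseline_value: float, scenario: OsmoticScenario, t: float,
                     param: str) -> float:
    """Parameter value at time ``t`` under the scenario's phase schedule.

    Within each phase the parameter relaxes exponentially toward the phase's
    asymptote (baseline × (1 + amplitude)); values are continuous across
    phase boundaries; t ≤ 0 lies in the baseline-repeat window.
    """
    if param not in RESPONSE_PARAMS:
        raise ValueError(f"unknown parameter {param!r}")
    if t < -float(scenario.baseline_repeats) or t > scenario.total_duration + 1e-9:
        raise ScheduleError(
            f"t = {t} min outside schedule [-{scenario.baseline_repeats}, "
            f"{scenario.total_duration}] min")
    if t <= 0:
        return baseline_value
    value = baseline_value
    for t0, t1, phase in scenario.phase_windows():
        resp = phase.response(param)
        asymptote = baseline_value * (1.0 + resp.amplitude)
        if t <= t1 + 1e-9:
            return asymptote + (value - asymptote) * math.exp(-(t - t0) / resp.tau_min)
        value = asymptote + (value - asymptote) * math.exp(-(t1 - t0) / resp.tau_min)
    return value  # pragma: no cover — unreachable given the range check


def _param_values(scenario: OsmoticScenario, geometry: EyeGeometry,
                  optics: TissueOptics, t: float) -> dict[str, float]:
    baselines = {
        "CCT": geometry.cct, "ACD": geometry.acd, "LT": geometry.lt,
        "CRD": geometry.crd, "LSI": optics.intensities.lens * optics.lens_multiplier,
        "IRIS_SAG": geometry.iris_sag,
    }
    return {p: osmotic_response(baselines[p], scenario, t, p)
            if not math.isnan(baselines[p]) else baselines[p]
            for p in RESPONSE_PARAMS}


def eye_at_time(scenario: OsmoticScenario, baseline_geometry: EyeGeometry,
                baseline_optics: TissueOptics, t: float
                ) -> tuple[EyeGeometry, TissueOptics]:
    """Instantiate the eye at time ``t``: CCT moves the posterior cornea,
    ACD translates the lens (iris follows), CRD moves the retina, the iris
    sag and the lens opacification multiplier follow their own responses."""
    v = _param_values(scenario, baseline_geometry, baseline_optics, t)
    g = baseline_geometry
    z_ca = g.cornea_anterior.apex_z
    cp = replace(g.cornea_posterior, apex_z=z_ca + v["CCT"])
    la = replace(g.lens_anterior, apex_z=cp.apex_z + v["ACD"])
    lp = replace(g.lens_posterior, apex_z=la.apex_z + v["LT"])
    ilm = replace(g.ilm, apex_z=cp.apex_z + v["CRD"])
    iris = None
    if g.iris is not None:
        wings = []
        for wing in g.iris:
            side = 1.0 if wing.root[0] >= g.axis_x else -1.0
            rx = g.axis_x + side * abs(wing.root[0] - g.axis_x)
            cx = g.axis_x + side * abs(wing.contact[0] - g.axis_x)
            wings.append(IrisWing(root=(rx, float(cp.z_at(rx))),
                                  contact=(cx, float(la.z_at(cx))),
                                  sag=v["IRIS_SAG"]))
        iris = (wings[0], wings[1])
    geometry = replace(g, cornea_posterior=cp, lens_anterior=la,
                       lens_posterior=lp, ilm=ilm, iris=iris).validate()
    lsi_baseline = baseline_optics.intensities.lens * baseline_optics.lens_multiplier
    optics = replace(baseline_optics, lens_multiplier=v["LSI"] / lsi_baseline
                     * baseline_optics.lens_multiplier)
    return geometry, optics


# ---------------------------------------------------------------------------
# forward rendering
# ---------------------------------------------------------------------------

def _intersect(p: np.ndarray, d: np.ndarray, surf: ArcSurface) -> Optional[float]:
    """Distance along the ray (p, d) to the arc, or None on a miss."""
    if surf.is_flat:
        if abs(d[1]) < 1e-12:
            return None
        s = (surf.apex_z - p[1]) / d[1]
        if s <= 1e-9:
            return None
        q = p + s * d
        return s if abs(q[0] - surf.apex_x) <= surf.half_width else None
    c = np.asarray(surf.center)
    m = p - c
    b = float(m @ d)
    disc = b * b - (float(m @ m) - surf.radius ** 2)
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    cz = c[1]
    best = None
    for s in (-b - sq, -b + sq):
        if s <= 1e-9:
            continue
        q = p + s * d
        on_branch = q[1] < cz if surf.radius > 0 else q[1] > cz
        if on_branch and abs(q[0] - surf.apex_x) <= surf.half_width:
            best = s if best is None else min(best, s)
    return best


def refract(d: np.ndarray, normal: np.ndarray, n1: float, n2: float
            ) -> Optional[np.ndarray]:
    """Vector Snell refraction; ``None`` signals total internal reflection."""
    nhat = normal if normal @ d < 0 else -normal
    eta = n1 / n2
    cos1 = -float(nhat @ d)
    sin2sq = eta * eta * (1.0 - cos1 * cos1)
    if sin2sq > 1.0:
        return None
    cos2 = math.sqrt(1.0 - sin2sq)
    out = eta * d + (eta * cos1 - cos2) * nhat
    return out / np.linalg.norm(out)


def _iris_hits(p: np.ndarray, d: np.ndarray, wing: IrisWing, thickness: float
               ) -> list[tuple[float, str]]:
    """Ray parameters where the ray crosses the wing's anterior surface and
    pigment epithelium (the wing curve itself)."""
    a0, b, c = wing.coefficients()
    hits = []
    for which, dz in (("anterior", -thickness), ("ipe", 0.0)):
        a = a0 + np.array([0.0, dz])
        # cross((a + b u + c u²) − p, d) = 0  → quadratic in u
        def cr(v):
            return v[0] * d[1] - v[1] * d[0]
        qa, qb, qc = cr(c), cr(b), cr(a - p)
        if abs(qa) < 1e-12:
            roots = [-qc / qb] if abs(qb) > 1e-12 else []
        else:
            disc = qb * qb - 4 * qa * qc
            if disc < 0:
                continue
            sq = math.sqrt(disc)
            roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
        for u in roots:
            if -1e-9 <= u <= 1 + 1e-9:
                q = a + b * u + c * u * u
                s = float((q - p) @ d) / float(d @ d)
                if s > 1e-9:
                    hits.append((s, which))
    hits.sort()
    return hits


@dataclass
class ColumnTrace:
    """Ray trace of one A-scan: interface crossings (label → optical-path
    depth, geometric point) and the ordered media segments in between."""

    crossings: dict[str, tuple[float, np.ndarray]]
    segments: list[tuple[float, float, str]]


def trace_column(geometry: EyeGeometry, optics: TissueOptics, x0: float
                 ) -> ColumnTrace:
    """Trace the probing ray entering at lateral position ``x0``."""
    p = np.array([x0, 0.0])
    d = _DOWN.copy()
    n_cur, opl = 1.0, 0.0
    crossings: dict[str, tuple[float, np.ndarray]] = {}
    events: list[tuple[float, str]] = [(0.0, "background")]
    index_after = optics.index_stack()
    media_after = {"cornea_anterior": "cornea", "cornea_posterior": "aqueous",
                   "lens_anterior": "lens", "lens_posterior": "vitreous",
                   "ilm": "retina"}
    skip_lens = False
    for label, surf in geometry.surfaces().items():
        if skip_lens and label == "lens_posterior":
            continue
        s = _intersect(p, d, surf)
        if label == "lens_anterior" and geometry.iris is not None:
            for wing, side in zip(geometry.iris, ("left", "right")):
                s_max = s if s is not None else math.inf
                hits = [(sh, w) for sh, w in
                        _iris_hits(p, d, wing, geometry.iris_thickness)
                        if 1e-9 < sh < s_max]
                # near the angle the band's anterior face lies within the
                # cornea: the band then starts right at the endothelium
                if any(w == "ipe" for _, w in hits) and \
                        not any(w == "anterior" for _, w in hits):
                    hits.insert(0, (1e-6, "anterior"))
                for s_hit, which in hits:
                    o_hit = opl + n_cur * s_hit
                    events.append((o_hit, "iris" if which == "anterior" else "aqueous"))
                    if which == "ipe":
                        crossings[f"iris_ipe_{side}"] = (o_hit, p + s_hit * d)
        if s is None:
            if label == "lens_anterior":
                skip_lens = True
            continue
        q = p + s * d
        opl = opl + n_cur * s
        crossings[label] = (opl, q)
        events.append((opl, media_after[label]))
        d_new = refract(d, surf.normal_at(q), n_cur, index_after[label])
        if d_new is not None:
            d = d_new
        p, n_cur = q, index_after[label]
    if "ilm" in crossings:
        events.append((crossings["ilm"][0] + geometry.retina_thickness * optics.n_retina,
                       "background"))
    events.sort(key=lambda e: e[0])
    segments = [(o0, o1, m) for (o0, m), (o1, _) in zip(events, events[1:]) if o1 > o0]
    segments.append((events[-1][0], math.inf, events[-1][1]))
    return ColumnTrace(crossings=crossings, segments=segments)


def _deposit(col: np.ndarray, o0: float, o1: float, intensity: float, pitch: float):
    """Add a constant-intensity optical segment [o0, o1) with partial-volume
    weighting at the fractional end pixels."""
    n = col.size
    a, b = max(o0, 0.0) / pitch, min(o1, n * pitch) / pitch
    if b <= a:
        return
    i0, i1 = int(a), min(int(b), n - 1)
    if i0 == i1:
        col[i0] += (b - a) * intensity
        return
    col[i0] += (i0 + 1 - a) * intensity
    col[i0 + 1:i1] += intensity
    if b > i1:
        col[i1] += (b - i1) * intensity


def _fill_column(trace: ColumnTrace, optics: TissueOptics, imaging: ImagingConfig
                 ) -> np.ndarray:
    col = np.zeros(imaging.n_rows)
    pitch = imaging.axial_pitch
    lens_bounds = None
    if "lens_anterior" in trace.crossings and "lens_posterior" in trace.crossings:
        lens_bounds = (trace.crossings["lens_anterior"][0],
                       trace.crossings["lens_posterior"][0])
    for o0, o1, medium in trace.segments:
        o1 = min(o1, imaging.depth)
        if o1 <= o0:
            continue
        base = optics.intensities.get(medium)
        if medium == "lens" and optics.lens_multiplier != 1.0 and lens_bounds:
            # smooth opacification front: anterior portion scaled by the
            # multiplier, sigmoid transition of width lens_front_width
            front = lens_bounds[0] + optics.lens_front_fraction * (lens_bounds[1] - lens_bounds[0])
            r0, r1 = int(max(o0, 0) / pitch), int(min(o1, imaging.depth) / pitch)
            rows = np.arange(r0, min(r1 + 1, imaging.n_rows))
            z = (rows + 0.5) * pitch
            prof = base * (1.0 + (optics.lens_multiplier - 1.0)
                           / (1.0 + np.exp(-(front - z) / optics.lens_front_width)))
            lo = np.clip((np.maximum(o0, rows * pitch)) / pitch - rows, 0, 1)
            hi = np.clip((np.minimum(o1, (rows + 1) * pitch)) / pitch - rows, 0, 1)
            col[rows] += prof * (hi - lo)
        else:
            _deposit(col, o0, o1, base, pitch)
    return col


def render_bscan(geometry: EyeGeometry, optics: TissueOptics,
                 imaging: ImagingConfig | None = None,
                 noise_seed: Optional[int] = None,
                 noise_model: NoiseModel | None = None,
                 timestamp: float = 0.0, phase: str = "") -> BScanImage:
    """Render one B-scan.  Deterministic when ``noise_seed`` is None; with a
    seed, multiplicative speckle and additive noise are applied on top of the
    identical noiseless image."""
    imaging = imaging or default_imaging()
    geometry.validate()
    data = np.zeros((imaging.n_rows, imaging.n_cols))
    for j, x0 in enumerate(imaging.x_coords()):
        trace = trace_column(geometry, optics, float(x0))
        if "ilm" in trace.crossings and trace.crossings["ilm"][0] >= imaging.depth:
            raise TruncationError(
                f"ILM at optical depth {trace.crossings['ilm'][0]:.0f} μm exceeds "
                f"image depth {imaging.depth:.0f} μm — deepen the image")
        data[:, j] = _fill_column(trace, optics, imaging)
    if noise_seed is not None:
        model = noise_model or NoiseModel()
        rng = np.random.default_rng(noise_seed)
        data = data * rng.gamma(model.speckle_looks, 1.0 / model.speckle_looks, data.shape)
        data = data + rng.normal(0.0, model.additive_sigma, data.shape)
        np.clip(data, 0.0, None, out=data)
    return BScanImage(data=data, axial_pitch=imaging.axial_pitch,
                      lateral_pitch=imaging.lateral_pitch,
                      timestamp=timestamp, phase=phase)


def render_meridian_stack(geometry: EyeGeometry, optics: TissueOptics,
                          imaging: ImagingConfig | None = None,
                          offsets: Sequence[float] = (-300.0, 0.0, 300.0),
                          noise_seed: Optional[int] = None) -> list[BScanImage]:
    """Thin stack of parallel cross-sections at vertical offsets from the
    vertex meridian, to exercise meridian-slice selection."""
    seeds = [None] * len(offsets)
    if noise_seed is not None:
        seeds = list(np.random.default_rng(noise_seed).integers(0, 2 ** 31 - 1, len(offsets)))
    return [render_bscan(geometry.at_meridian(dy), optics, imaging, noise_seed=s)
            for dy, s in zip(offsets, seeds)]


def render_timeseries(scenario: OsmoticScenario,
                      baseline_geometry: EyeGeometry | None = None,
                      baseline_optics: TissueOptics | None = None,
                      imaging: ImagingConfig | None = None,
                      seed: Optional[int] = None,
                      noise: bool = False,
                      noise_model: NoiseModel | None = None
                      ) -> tuple[list[BScanImage], pd.DataFrame]:
    """Render the scenario's full acquisition schedule.

    Returns the frames plus a ground-truth table of the six biometric
    parameters at each timestamp.  All randomness derives from ``seed``.
    """
    if baseline_geometry is None or baseline_optics is None:
        g0, o0 = baseline_for(scenario.preset)
        baseline_geometry = baseline_geometry or g0
        baseline_optics = baseline_optics or o0
    if imaging is None:
        imaging = default_imaging(scenario.preset, **{k: v for k, v in scenario.imaging.items()})
    times = scenario.frame_times()
    frame_seeds: list[Optional[int]] = [None] * len(times)
    if noise:
        rng = np.random.default_rng(seed)
        frame_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, len(times))]
    frames, truth = [], []
    for (t, label), fseed in zip(times, frame_seeds):
        geom, opt = eye_at_time(scenario, baseline_geometry, baseline_optics, t)
        frames.append(render_bscan(geom, opt, imaging, noise_seed=fseed,
                                   noise_model=noise_model, timestamp=t, phase=label))
        v = _param_values(scenario, baseline_geometry, baseline_optics, t)
        truth.append({"t_min": t, "phase": label, "CCT": v["CCT"], "ACD": v["ACD"],
                      "LT": v["LT"], "CRD": v["CRD"], "LSI": v["LSI"],
                      "IC": v["IRIS_SAG"]})
    return frames, pd.DataFrame(truth)
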
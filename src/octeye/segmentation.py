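"""Surface detection in B-scans (semiautomatic).

Boundaries are found per A-scan as peaks of the axial intensity gradient
above an Otsu-derived threshold, then assigned to anatomical labels by
ordered, intensity-aware classification: the first two peaks bound the
cornea; high-backscatter bands identify the iris body (shallow) and the
retina (deep, its top edge being the ILM); the remaining peaks between
them bound the crystalline lens.  Optional per-surface seed points
constrain the assignment, which is what makes the procedure semiautomatic.

Coordinates: lateral position in μm (0 at image centre), axial depth in μm
of optical path; pixel indices never leave this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .errors import DetectionError
from .phantom import BScanImage

AXIAL_LABELS = ("cornea_anterior", "cornea_posterior", "lens_anterior",
                "lens_posterior", "ilm")
IRIS_LABELS = ("iris_ipe_left", "iris_ipe_right")
ALL_LABELS = AXIAL_LABELS + IRIS_LABELS


@dataclass
class SurfaceSet:
    """Segmented surface traces in image (optical-path) coordinates.

    ``traces`` maps label → (N, 2) array of (lateral x μm, axial optical
    depth μm), sorted by x.  ``missing`` reports surfaces that could not be
    detected — never silently omitted."""

    traces: dict[str, np.ndarray]
    axial_pitch: float
    lateral_pitch: float
    axis_x: Optional[float] = None
    vertex: Optional[tuple[float, float]] = None
    missing: tuple[str, ...] = ()
    notes: dict = field(default_factory=dict)

    def has(self, label: str) -> bool:
        return label in self.traces and len(self.traces[label]) >= 2

    def z_at(self, label: str, x: float | np.ndarray) -> np.ndarray | float:
        """Interpolated optical depth of a trace at lateral position x."""
        tr = self.traces[label]
        return np.interp(x, tr[:, 0], tr[:, 1])

    def check_order(self) -> "SurfaceSet":
        """Drop points violating the anatomical depth order column-wise."""
        present = [l for l in AXIAL_LABELS if self.has(l)]
        for shallow, deep in zip(present, present[1:]):
            td = self.traces[deep]
            zs = self.z_at(shallow, td[:, 0])
            keep = td[:, 1] > zs
            if not np.all(keep):
                self.traces[deep] = td[keep]
        return self


def _column_candidates(mag: np.ndarray, floor: float,
                       local: Optional[np.ndarray] = None,
                       rel: float = 0.2, min_sep: int = 4) -> np.ndarray:
    """Sub-pixel rows of gradient-magnitude peaks in one A-scan column.

    A peak qualifies when it clears the global noise ``floor`` and, if the
    smoothed intensity profile ``local`` is given, also ``rel`` times the
    local intensity — speckle is multiplicative, so its gradients scale
    with layer brightness while a true boundary's gradient scales with the
    intensity *step*."""
    peaks, _ = find_peaks(mag, height=floor, distance=min_sep)
    if local is not None and peaks.size:
        peaks = peaks[mag[peaks] >= rel * local[peaks]]
    if peaks.size == 0:
        return peaks.astype(float)
    out = []
    for p in peaks:
        if 0 < p < mag.size - 1:
            y0, y1, y2 = mag[p - 1], mag[p], mag[p + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            out.append(p + float(np.clip(shift, -0.5, 0.5)))
        else:
            out.append(float(p))
    return np.asarray(out)


def _interval_median(col: np.ndarray, a: float, b: float) -> float:
    lo, hi = int(np.ceil(a)) + 1, int(np.floor(b)) - 1
    hi = min(hi, col.size - 1)
    if hi < lo:
        mid = int(round((a + b) / 2))
        return float(col[np.clip(mid, 0, col.size - 1)])
    return float(np.median(col[lo:hi + 1]))


def _clean_trace(arr: np.ndarray, axial_pitch: float,
                 window: int = 9, tol_pixels: float = 4.0) -> np.ndarray:
    """Reject trace points far from a rolling median of their neighbours —
    surfaces are laterally smooth, mis-assigned speckle peaks are not."""
    if len(arr) < window:
        return arr
    med = median_filter(arr[:, 1], size=window, mode="nearest")
    keep = np.abs(arr[:, 1] - med) <= tol_pixels * axial_pitch
    return arr[keep] if keep.sum() >= 3 else arr


def _noise_floor(mag: np.ndarray) -> float:
    """Global gradient noise floor: a multiple of the median gradient
    magnitude, refined by Otsu's split of the sub-edge population."""
    med = float(np.median(mag))
    floor = 4.0 * med + 1e-9
    if med > 0:
        try:
            weak = mag[mag < 0.25 * mag.max()]
            floor = max(floor, 0.5 * float(threshold_otsu(weak)))
        except ValueError:
            pass
    return floor


def detect_surfaces(image: BScanImage,
                    seeds: Optional[Mapping[str, tuple[float, float]]] = None,
                    smooth_sigma: tuple[float, float] = (1.5, 1.5),
                    bright_fraction: float = 0.55,
                    min_points: int = 5) -> SurfaceSet:
    """Detect the ocular surfaces and the iris pigment epithelium.

    ``seeds`` optionally maps a label to an approximate (x μm, z μm) point;
    the seeded label is then re-assigned to the gradient peak nearest the
    seed depth in every column (±300 μm window).
    """
    img = np.asarray(image.data, dtype=float)
    if img.size == 0 or not np.any(img > 0):
        raise DetectionError("empty or all-zero image")
    sm = gaussian_filter(img, smooth_sigma)
    mag = np.abs(np.gradient(sm, axis=0))
    if mag.max() <= 0:
        raise DetectionError("image has no axial structure")
    floor = _noise_floor(mag)

    xs = image.x_coords()
    ncols = img.shape[1]
    cand_by_col = [_column_candidates(mag[:, j], floor)
                   for j in range(ncols)]

    # reference brightness = the strongest inter-boundary band median in the
    # image (iris body if present, otherwise retina); intensity levels are
    # classified relative to it
    band_meds = []
    med_by_col: list[np.ndarray] = []
    for j in range(ncols):
        c = cand_by_col[j]
        if c.size < 2:
            med_by_col.append(np.empty(0))
            continue
        edges = list(c) + [c[-1] + 20.0]
        meds = np.asarray([_interval_median(sm[:, j], edges[i], edges[i + 1])
                           for i in range(len(c))])
        med_by_col.append(meds)
        band_meds.extend(meds[1:])
    if not band_meds:
        raise DetectionError("no boundaries found below the corneal surface")
    ref = max(band_meds)
    bright_thr = bright_fraction * ref
    mid_thr = 0.25 * ref

    points: dict[str, list[tuple[float, float]]] = {l: [] for l in
                                                    AXIAL_LABELS + ("iris_ipe", "iris_anterior")}
    for j in range(ncols):
        c = cand_by_col[j]
        if c.size < 2:
            continue
        x = float(xs[j])
        meds = med_by_col[j]
        # level of the band following each candidate: 2 bright / 1 mid / 0 dark
        level = np.where(meds > bright_thr, 2, np.where(meds > mid_thr, 1, 0))
        points["cornea_anterior"].append((x, c[0]))
        # cornea = leading non-dark run; its end is the posterior surface
        k = 1
        while k < c.size and level[k] >= 1:
            k += 1
        if k >= c.size:
            continue
        points["cornea_posterior"].append((x, c[k]))
        # contiguous bright runs below the cornea: deepest = retina (its top
        # edge is the ILM); the strongest clearly-anterior one = iris body.
        # Runs separated by thin gaps (speckle splitting a bright band) are
        # merged before assignment.
        runs: list[list[int]] = []
        for i in range(k + 1, c.size):
            if level[i] == 2:
                if runs and i == runs[-1][-1] + 1:
                    runs[-1].append(i)
                else:
                    runs.append([i])
        merged: list[list[int]] = []
        for run in runs:
            prev_end = merged[-1][-1] + 1 if merged else None
            if prev_end is not None and prev_end < c.size and \
                    c[run[0]] - c[prev_end] < 10.0:
                merged[-1] = merged[-1] + run
            else:
                merged.append(run)
        if not merged:
            continue
        ret_run = merged[-1]
        r = ret_run[0]
        points["ilm"].append((x, c[r]))
        lo = k
        # iris must lie well anterior of the retina, not be a speckle
        # artefact at its rim
        iris_runs = [run for run in merged[:-1] if c[run[0]] < 0.7 * c[r]]
        if iris_runs:
            k_run = max(iris_runs, key=lambda run: max(meds[i] for i in run))
            points["iris_anterior"].append((x, c[k_run[0]]))
            if k_run[-1] + 1 < c.size:
                points["iris_ipe"].append((x, c[k_run[-1] + 1]))
                lo = k_run[-1] + 1
        # crystalline lens = mid-level run strictly between (iris or cornea)
        # and the retina
        mid_idx = [i for i in range(lo + 1, r) if level[i] == 1]
        if mid_idx and mid_idx[-1] + 1 <= r:
            points["lens_anterior"].append((x, c[mid_idx[0]]))
            points["lens_posterior"].append((x, c[mid_idx[-1] + 1]))

    if seeds:
        for label, (sx, sz) in seeds.items():
            key = label if label in points else None
            if key is None:
                continue
            picked = []
            for j in range(ncols):
                c = cand_by_col[j] * image.axial_pitch
                if c.size == 0:
                    continue
                k = int(np.argmin(np.abs(c - sz)))
                if abs(c[k] - sz) <= 300.0:
                    picked.append((float(xs[j]), c[k] / image.axial_pitch))
            if picked:
                points[key] = picked

    traces: dict[str, np.ndarray] = {}
    for label, pts in points.items():
        if pts:
            arr = np.asarray(pts, dtype=float)
            arr[:, 1] *= image.axial_pitch
            arr = arr[np.argsort(arr[:, 0])]
            traces[label] = _clean_trace(arr, image.axial_pitch)

    if "cornea_anterior" not in traces or len(traces["cornea_anterior"]) < min_points:
        raise DetectionError("corneal anterior surface not detected")

    ss = SurfaceSet(traces=traces, axial_pitch=image.axial_pitch,
                    lateral_pitch=image.lateral_pitch)
    ss.axis_x, ss.vertex = locate_vertex(ss)

    # split the iris pigment epithelium into wings about the AP axis
    if "iris_ipe" in ss.traces:
        ipe = ss.traces.pop("iris_ipe")
        left, right = ipe[ipe[:, 0] < ss.axis_x], ipe[ipe[:, 0] > ss.axis_x]
        if len(left):
            ss.traces["iris_ipe_left"] = left
        if len(right):
            ss.traces["iris_ipe_right"] = right
    ss.traces.pop("iris_anterior", None)

    ss.check_order()
    ss.missing = tuple(l for l in ALL_LABELS
                       if l not in ss.traces or len(ss.traces[l]) <
                       (min_points if l in AXIAL_LABELS else 3))
    return ss


def locate_vertex(surfaces: SurfaceSet) -> tuple[float, tuple[float, float]]:
    """Corneal vertex = minimal-depth point of the anterior corneal trace;
    the AP axis is the vertical line through it.

    A local quadratic fit around the discrete minimum gives sub-pixel
    lateral position; a flat trace with no unique minimum falls back to the
    lateral midpoint of the trace."""
    if not surfaces.has("cornea_anterior"):
        raise DetectionError("corneal anterior trace required to locate the vertex")
    tr = surfaces.traces["cornea_anterior"]
    x, z = tr[:, 0], tr[:, 1]
    if z.max() - z.min() < 0.25 * surfaces.axial_pitch:   # flat: tie-break
        vx = float(0.5 * (x.min() + x.max()))
        return vx, (vx, float(np.median(z)))
    i = int(np.argmin(z))
    lo, hi = max(0, i - 4), min(len(x), i + 5)
    if hi - lo >= 3:
        coeff = np.polyfit(x[lo:hi], z[lo:hi], 2)
        if coeff[0] > 0:
            vx = float(-coeff[1] / (2 * coeff[0]))
            if x[lo] <= vx <= x[hi - 1]:
                vz = float(np.polyval(coeff, vx))
                return vx, (vx, vz)
    return float(x[i]), (float(x[i]), float(z[i]))


def select_meridian_slice(volume: Sequence[BScanImage]) -> BScanImage:
    """Pick the vertex-containing slice: the one whose corneal anterior
    apex is shallowest.  Ties resolve to the lowest index."""
    if len(volume) == 0:
        raise DetectionError("empty volume")
    best_idx, best_depth = None, np.inf
    for i, im in enumerate(volume):
        img = np.asarray(im.data, dtype=float)
        if not np.any(img > 0):
            continue
        sm = gaussian_filter(img, (1.5, 1.5))
        mag = np.abs(np.gradient(sm, axis=0))
        if mag.max() <= 0:
            continue
        floor = _noise_floor(mag)
        depths = []
        for j in range(img.shape[1]):
            c = _column_candidates(mag[:, j], floor, local=sm[:, j])
            if c.size:
                depths.append(c[0])
        if depths:
            apex = min(depths) * im.axial_pitch
            if apex < best_depth - 1e-9:
                best_idx, best_depth = i, apex
    if best_idx is None:
        raise DetectionError("no detectable cornea in any slice")
    return volume[best_idx]
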
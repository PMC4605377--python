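"""Response dynamics: baseline normalization, peak change, exponential fits
and steady-state detection on per-frame biometry records.

Every parameter is expressed as a percentage change from its baseline (the
mean of the pre-challenge repeat acquisitions); a phase's response is then
summarized by its signed extreme change, a fitted exponential relaxation
A·(1 − e^(−(t−t0)/τ)), and the time at which the change rate first drops
below 1 % of the initial rate (the steady-state rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import MeasurementError
from .scenario import OsmoticScenario

PARAMS = ("CCT", "ACD", "LT", "CRD", "LSI", "IC")


def compute_baseline(records: pd.DataFrame, n_repeats: int = 5,
                     params: tuple[str, ...] = PARAMS) -> pd.DataFrame:
    """Per-parameter mean and SD of the first ``n_repeats`` acquisitions."""
    if n_repeats < 1:
        raise MeasurementError("baseline needs at least one repeat")
    if len(records) < n_repeats:
        raise MeasurementError(
            f"only {len(records)} records for {n_repeats} baseline repeats")
    head = records.sort_values("t_min").head(n_repeats)
    rows = [{"param": p, "mean": float(head[p].mean()), "sd": float(head[p].std(ddof=0))}
            for p in params if p in head]
    return pd.DataFrame(rows).set_index("param")


def normalize(values: np.ndarray | float, baseline: float) -> np.ndarray | float:
    """Percent change from baseline: 100·(p − p0)/p0."""
    if not baseline > 0:
        raise MeasurementError(f"baseline must be positive, got {baseline}")
    return 100.0 * (np.asarray(values, dtype=float) - baseline) / baseline \
        if np.ndim(values) else 100.0 * (values - baseline) / baseline


def denormalize(pct: np.ndarray | float, baseline: float) -> np.ndarray | float:
    """Inverse of :func:`normalize`."""
    if not baseline > 0:
        raise MeasurementError(f"baseline must be positive, got {baseline}")
    return baseline * (1.0 + np.asarray(pct, dtype=float) / 100.0) \
        if np.ndim(pct) else baseline * (1.0 + pct / 100.0)


def peak_change(t: np.ndarray, pct: np.ndarray) -> tuple[float, float]:
    """Signed extreme of the normalized series and its time; earliest wins
    on ties (``argmax`` of the absolute value)."""
    t, pct = np.asarray(t, dtype=float), np.asarray(pct, dtype=float)
    if t.size < 2:
        raise MeasurementError("peak change needs at least 2 frames")
    i = int(np.argmax(np.abs(pct)))
    return float(pct[i]), float(t[i])


@dataclass
class ExponentialFit:
    amplitude: float = math.nan   # asymptotic change, same units as the series
    tau: float = math.nan         # minutes
    rms: float = math.nan
    converged: bool = False


def fit_exponential(t: np.ndarray, y: np.ndarray) -> ExponentialFit:
    """Least-squares fit of y(t) = y(t0) + A·(1 − e^(−(t−t0)/τ)).

    Non-convergence is flagged, never raised — the raw series stays usable.
    """
    t, y = np.asarray(t, dtype=float), np.asarray(y, dtype=float)
    if t.size < 4:
        raise MeasurementError("exponential fit needs at least 4 frames")
    dt, dy = t - t[0], y - y[0]

    def model(x, a, tau):
        return a * (1.0 - np.exp(-x / tau))

    span = max(dt[-1], 1e-6)
    a0 = dy[-1] if abs(dy[-1]) > 1e-12 else 1e-3
    try:
        popt, _ = curve_fit(model, dt, dy, p0=[a0, span / 3],
                            bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
                            maxfev=10000)
    except (RuntimeError, ValueError):
        return ExponentialFit()
    rms = float(np.sqrt(np.mean((model(dt, *popt) - dy) ** 2)))
    return ExponentialFit(amplitude=float(popt[0]), tau=float(popt[1]),
                          rms=rms, converged=True)


def steady_state_time(t: np.ndarray, y: np.ndarray,
                      rate_fraction: float = 0.01) -> Optional[float]:
    """Earliest time the |change rate| falls below ``rate_fraction`` of the
    initial rate; ``None`` if never reached within the segment.

    Rates are centred finite differences of a 3-frame moving average; the
    initial rate is the first interior window's.  A constant series has
    zero initial rate and is steady immediately (returns t[0]).  For an
    exact exponential this lands at t0 + τ·ln(1/rate_fraction).
    """
    t, y = np.asarray(t, dtype=float), np.asarray(y, dtype=float)
    if t.size < 3:
        raise MeasurementError("steady-state detection needs at least 3 frames")
    ys = y.astype(float).copy()
    ys[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0   # 3-frame moving window
    rate = np.gradient(ys, t)
    r0 = abs(rate[1])
    scale = max(np.max(np.abs(y)), 1.0)
    if r0 < 1e-12 * scale:
        return float(t[0])
    below = np.abs(rate[1:]) < rate_fraction * r0
    idx = np.flatnonzero(below)
    return float(t[idx[0] + 1]) if idx.size else None


@dataclass
class ResponseSeries:
    """One parameter's normalized response over a whole run."""

    param: str
    t: np.ndarray
    values: np.ndarray
    baseline: float
    baseline_sd: float
    pct: np.ndarray = field(init=False)

    def __post_init__(self):
        self.pct = np.asarray(normalize(self.values, self.baseline))


def summarize_run(records: pd.DataFrame, scenario: OsmoticScenario,
                  params: tuple[str, ...] = PARAMS) -> pd.DataFrame:
    """Per-parameter, per-phase summary of a measured run.

    For each challenge phase: the signed peak change (%), its time, the
    fitted exponential amplitude and τ, and the steady-state time.
    """
    df = records.sort_values("t_min").reset_index(drop=True)
    base = compute_baseline(df, scenario.baseline_repeats, params)
    rows = []
    for p in params:
        if p not in df or p not in base.index:
            continue
        b = base.loc[p]
        if not b["mean"] > 0 or not np.isfinite(df[p]).all():
            continue
        series = ResponseSeries(p, df["t_min"].to_numpy(), df[p].to_numpy(),
                                float(b["mean"]), float(b["sd"]))
        for i, (t0, t1, phase) in enumerate(scenario.phase_windows()):
            m = (series.t > t0 + 1e-9) & (series.t <= t1 + 1e-9)
            if m.sum() < 2:
                continue
            pk, tpk = peak_change(series.t[m], series.pct[m])
            fit = ExponentialFit()
            if m.sum() >= 4:
                fit = fit_exponential(series.t[m], series.pct[m])
            # asymptotic change relative to baseline: the fitted amplitude is
            # relative to the first in-phase frame, which has already moved
            asymptote = series.pct[m][0] + fit.amplitude
            sst = steady_state_time(series.t[m], series.pct[m]) if m.sum() >= 3 else None
            rows.append({"param": p, "phase": phase.display_label(i),
                         "tonicity": phase.tonicity, "t_start": t0, "t_end": t1,
                         "baseline": series.baseline, "baseline_sd": series.baseline_sd,
                         "peak_pct": pk, "t_peak": tpk,
                         "fit_amplitude_pct": fit.amplitude,
                         "fit_asymptote_pct": asymptote, "fit_tau_min": fit.tau,
                         "fit_rms": fit.rms, "fit_converged": fit.converged,
                         "steady_state_min": sst if sst is not None else math.nan})
    return pd.DataFrame(rows)


#: Parameters whose normalized response curves define run stability.  The
#: iris curvature is not a normalized curve parameter: it is reported in
#: absolute μm at sparse time points and judged on its own.
CURVE_PARAMS = ("CCT", "ACD", "LT", "CRD", "LSI")


def control_fluctuation(records: pd.DataFrame, scenario: OsmoticScenario,
                        params: tuple[str, ...] = CURVE_PARAMS) -> float:
    """Mean over the curve parameters of the SD of the normalized
    fluctuations (%) — the stability figure a control run is judged by."""
    df = records.sort_values("t_min")
    base = compute_baseline(df, scenario.baseline_repeats, params)
    sds = []
    for p in params:
        if p in df and p in base.index and base.loc[p, "mean"] > 0:
            pct = normalize(df[p].to_numpy(), float(base.loc[p, "mean"]))
            sds.append(float(np.std(pct)))
    if not sds:
        raise MeasurementError("no usable parameters for control fluctuation")
    return float(np.mean(sds))
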
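"""Cardiovascular biomarkers from optoacoustic amplitude trends.

The device reports peak-to-peak signal amplitudes in regions of interest over
time; because the optoacoustic amplitude at a fixed wavelength tracks local
optical absorption, those trends carry physiology:

* hypoxia — amplitude is linear in blood oxygen saturation (sO₂), so a
  least-squares line against an oximeter reference calibrates mV per % sO₂;
* exogenous-agent washout — the blood signal, referenced to the surrounding
  tissue baseline, decays exponentially with the agent's clearance rate;
* venous compliance — finite differences ΔR/ΔP of the occlusion amplitude
  ratio against cuff pressure (points at ≤ 40 mmHg are excluded: below the
  resting venous pressure the vessel flattens and the ratio is invalid);
* flow-mediated dilation — relative signal change p_A at the post-release
  peak converts to a diameter change via sqrt(1 + p_A) − 1, since the signal
  is proportional to the vessel's cross-sectional area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import ChannelData, ReconVolume, TrendSeries
from .errors import FitError, UsageError
from .metrics import ROISpec

PRESSURE_VALIDITY_MMHG = 40.0


@dataclass
class SO2Calibration:
    slope: float  # mV per % sO2
    intercept: float  # mV
    r_squared: float


@dataclass
class DecayFit:
    decay_coefficient: float  # s^-1
    r_squared: float
    rms_agreement_pct: float
    amplitude: float
    offset: float


@dataclass
class ComplianceResult:
    """ΔR/ΔP per pressure interval, with the excluded low-pressure points."""

    dR_dP: np.ndarray  # % per mmHg, one per interval
    intervals: list[tuple[float, float]]
    ratios: np.ndarray
    pressures: np.ndarray
    excluded: list[tuple[float, float]]


@dataclass
class FMDResult:
    p_A: float
    diameter_change: float


def extract_trend(
    frames,
    roi: ROISpec | None = None,
    window: int = 5,
    frame_rate: float = 10.0,
    roi_label: str = "vein",
) -> TrendSeries:
    """Per-frame peak-to-peak amplitude inside an ROI, optionally smoothed.

    ``frames`` is a sequence of ReconVolume (ROI masks voxels) or ChannelData
    (ROI masks elements; peak-to-peak over the trace window).  ``window`` is
    the moving-average length in frames (1 disables smoothing); the default 5
    frames at the 10 Hz frame rate is a 0.5 s smoother.
    """
    values = []
    for fr in frames:
        if isinstance(fr, ReconVolume):
            v = fr.voxels[roi.signal] if roi is not None else fr.voxels
        elif isinstance(fr, ChannelData):
            if roi is not None:
                v = fr.samples.reshape(-1, fr.n_times)[roi.signal.ravel()]
            else:
                v = fr.samples
        else:
            v = np.asarray(fr)
        if v.size == 0:
            raise UsageError("empty ROI")
        values.append(float(np.max(v) - np.min(v)))
    values = np.asarray(values)
    if window > 1:
        kernel = np.ones(window) / window
        pad = np.concatenate(
            [np.full(window // 2, values[0]), values,
             np.full(window - 1 - window // 2, values[-1])]
        )
        values = np.convolve(pad, kernel, mode="valid")
    t = np.arange(len(values)) / frame_rate
    return TrendSeries(timestamps=t, values=values, roi=roi_label)


def fit_so2_linear(trend: TrendSeries, so2_reference: np.ndarray) -> SO2Calibration:
    """Least-squares line of amplitude (mV) against reference sO₂ (%)."""
    so2 = np.asarray(so2_reference, dtype=float)
    if len(so2) != len(trend.values) or len(so2) < 3:
        raise UsageError("need >= 3 paired amplitude/sO2 points")
    if np.ptp(so2) == 0:
        raise FitError("reference sO2 has no variance")
    res = stats.linregress(so2, trend.values)
    return SO2Calibration(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def fit_decay(trend: TrendSeries, baseline: TrendSeries) -> DecayFit:
    """Exponential clearance fit of a blood trend against a tissue baseline.

    The blood trend is divided by the time-aligned, start-normalized tissue
    baseline (removing shared drifts of illumination and coupling), then
    A·e^(−k t) + C is fitted.  Reports k, R², and the RMS agreement
    100·(1 − RMSE/mean).
    """
    t0 = max(trend.timestamps[0], baseline.timestamps[0])
    t1 = min(trend.timestamps[-1], baseline.timestamps[-1])
    if t1 <= t0:
        raise UsageError("trend and baseline do not overlap in time")
    sel = (trend.timestamps >= t0) & (trend.timestamps <= t1)
    t = trend.timestamps[sel]
    base = np.interp(t, baseline.timestamps, baseline.values)
    if np.any(base <= 0):
        raise FitError("baseline crosses zero; cannot normalize")
    y = trend.values[sel] / (base / base[0])
    if np.mean(y <= 0) > 0.05:
        raise FitError("adjusted trend is non-positive beyond tolerance")

    ts = t - t[0]
    span = max(ts[-1], 1.0)
    # log-linear seed for the nonlinear fit
    ypos = np.clip(y, np.max(y) * 1e-6, None)
    k0 = max(-np.polyfit(ts, np.log(ypos), 1)[0], 1e-8)

    def model(tt, a, k, c):
        return a * np.exp(-k * tt) + c

    p0 = (float(y[0] - y[-1]) or float(np.ptp(y)) or 1.0, k0, float(y[-1]))
    try:
        popt, _ = optimize.curve_fit(model, ts, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"decay fit did not converge: {exc}") from exc
    a, k, c = popt
    resid = y - model(ts, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rms = 100.0 * (1.0 - np.sqrt(ss_res / len(y)) / float(np.mean(y)))
    return DecayFit(
        decay_coefficient=float(k), r_squared=float(r2),
        rms_agreement_pct=float(rms), amplitude=float(a), offset=float(c),
    )


def compliance(ratios: np.ndarray, pressures: np.ndarray) -> ComplianceResult:
    """Venous compliance ΔR/ΔP (% per mmHg) between successive valid pressures.

    Only amplitude ratios recorded at occlusion pressures above 40 mmHg are
    valid; excluded points are reported in the result.
    """
    r = np.asarray(ratios, dtype=float)
    p = np.asarray(pressures, dtype=float)
    if r.shape != p.shape or r.ndim != 1:
        raise UsageError("ratios and pressures must be matching 1D arrays")
    valid = p > PRESSURE_VALIDITY_MMHG
    excluded = [(float(pp), float(rr)) for pp, rr in zip(p[~valid], r[~valid])]
    r, p = r[valid], p[valid]
    if len(p) < 2:
        raise UsageError("need >= 2 valid (>40 mmHg) pressure points")
    order = np.argsort(p)
    r, p = r[order], p[order]
    if np.any(np.diff(p) == 0):
        raise UsageError("pressure intervals must be non-degenerate")
    slopes = np.diff(r) / np.diff(p)
    intervals = [(float(a), float(b)) for a, b in zip(p[:-1], p[1:])]
    return ComplianceResult(
        dR_dP=slopes, intervals=intervals, ratios=r, pressures=p,
        excluded=excluded,
    )


def fmd_diameter_change(p_A: float) -> float:
    """Fractional diameter change sqrt(1 + p_A) − 1 from the relative signal
    change at the post-release peak (signal ∝ cross-sectional area)."""
    if p_A <= -1.0:
        raise UsageError("relative signal change must exceed −1")
    return float(np.sqrt(1.0 + p_A) - 1.0)
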
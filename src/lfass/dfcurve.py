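"""Death-fluorescence curve analysis: from a raw well trace to the median
time of death.

A dying nematode releases a burst of endogenous blue fluorescence; the
population trace therefore rises sigmoidally as worms die, peaks, and then
decays as individual bursts fade. The time at which the rising phase
crosses half of the peak fluorescence estimates the population's median
time of death. The pipeline per well is:

1. ``preprocess`` — interpolate short dropouts, smooth (moving median then
   moving mean), estimate the per-read noise scale and a provisional
   baseline.
2. ``detect_peak`` — find the most prominent local maximum whose prominence
   exceeds a noise-scaled threshold; no significant peak means the well is
   unfittable (dead-on-arrival, empty, or saturated wells).
3. ``normalize`` — min-max normalize the rising phase between a pre-rise
   baseline and the peak.
4. ``fit_half_max`` — either fit a 4-parameter logistic to the rising phase
   (``auto``, the default) and report its midpoint, or linearly interpolate
   the first upward half-maximum crossing (``interpolation``, the
   equivalent of manual curve reading).
5. ``classify_fit`` — final QC status: OK, REVIEW (borderline fit, queued
   for human re-analysis) or UNFIT.

Everything here is deterministic; randomness lives in :mod:`lfass.simkit`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.signal import find_peaks

from .errors import ConfigError
from .plate_io import PlateRun, RawTrace, TimeGrid

log = logging.getLogger("lfass.dfcurve")

__all__ = [
    "FitParams", "ProcessedTrace", "PeakCall", "FitResult",
    "preprocess", "detect_peak", "normalize", "fit_half_max",
    "classify_fit", "batch_fit",
    "STATUS_OK", "STATUS_REVIEW", "STATUS_UNFIT",
]

STATUS_OK = "OK"
STATUS_REVIEW = "REVIEW"
STATUS_UNFIT = "UNFIT"

# reason codes attached to FitResult.flags
MISSING_DATA = "MISSING_DATA"
NO_SIGNIFICANT_PEAK = "NO_SIGNIFICANT_PEAK"
NO_DYNAMIC_RANGE = "NO_DYNAMIC_RANGE"
NO_HALF_CROSSING = "NO_HALF_CROSSING"
OUT_OF_WINDOW = "OUT_OF_WINDOW"
HIGH_RMSE = "HIGH_RMSE"
FALLBACK_INTERP = "FALLBACK_INTERP"
SATURATED = "SATURATED"


@dataclass(frozen=True)
class FitParams:
    """Tunable analysis parameters.

    smooth_window : odd sample count of both smoothing stages (median, then
        mean). 1 disables smoothing.
    baseline_quantile : quantile of the pre-peak smoothed signal used as the
        fluorescence baseline.
    min_prominence_mads : significance threshold for peaks, in units of the
        robust per-read noise scale.
    rmse_review / rmse_unfit : relative fit-residual thresholds (rmse over
        fitted amplitude) above which a well is queued for review /
        declared unfittable.
    analysis_window : optional (t_start, t_end) in minutes restricting the
        analysis to part of the recording.
    saturation_fraction : fraction of reads exactly at the trace maximum
        above which the detector is assumed saturated (flagged, REVIEW).
    """

    smooth_window: int = 5
    baseline_quantile: float = 0.05
    min_prominence_mads: float = 5.0
    rmse_review: float = 0.15
    rmse_unfit: float = 0.30
    analysis_window: tuple[float, float] | None = None
    saturation_fraction: float = 0.05

    def __post_init__(self):
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError(f"smooth_window must be odd and >= 1, got {self.smooth_window}")
        if not 0 < self.baseline_quantile < 0.5:
            raise ConfigError("baseline_quantile must be in (0, 0.5)")
        if self.min_prominence_mads < 0:
            raise ConfigError("min_prominence_mads must be >= 0")
        if not 0 < self.rmse_review <= self.rmse_unfit:
            raise ConfigError("need 0 < rmse_review <= rmse_unfit")


@dataclass
class ProcessedTrace:
    """Smoothed trace with baseline, noise scale and analysis window."""

    well_id: str
    grid: TimeGrid
    f_smooth: np.ndarray
    baseline: float
    window: tuple[float, float]
    noise_sigma: float = 0.0
    valid: bool = True
    flags: set = field(default_factory=set)

    def window_slice(self) -> slice:
        t = self.grid.times
        i0 = int(np.searchsorted(t, self.window[0], side="left"))
        i1 = int(np.searchsorted(t, self.window[1], side="right"))
        return slice(i0, i1)


@dataclass(frozen=True)
class PeakCall:
    """The selected significant fluorescence peak of a well (if any)."""

    t_peak: float
    f_peak: float
    prominence: float
    window: tuple[float, float]
    significant: bool


@dataclass
class FitResult:
    """Per-well outcome: estimated median time of death plus diagnostics.

    ``t_half`` is None whenever ``status == UNFIT``; the last computed
    value (if any) is kept under ``diagnostics['t_half_raw']``.
    """

    well_id: str
    t_half: float | None = None
    method: str = "auto"                      # 'sigmoid_fit' | 'interpolation'
    params: dict = field(default_factory=dict)  # F0, A, t50, k of the logistic
    rmse: float = float("nan")
    status: str = STATUS_UNFIT
    flags: set = field(default_factory=set)
    t_peak: float | None = None
    peak_prominence: float | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# 1. preprocessing


def _interpolate_gaps(f: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Fill NaN runs (validated to be <= 2 long upstream) linearly."""
    if not np.isnan(f).any():
        return f
    out = f.copy()
    ok = ~np.isnan(f)
    out[~ok] = np.interp(t[~ok], t[ok], f[ok])
    return out


def _smooth(f: np.ndarray, window: int) -> np.ndarray:
    """Moving median then moving mean, both with the same odd window.

    The median stage removes isolated single-read spikes (bubbles,
    condensation); the mean stage stabilizes the subsequent fit. Edges use
    nearest-value padding.
    """
    if window == 1:
        return f.copy()
    return uniform_filter1d(median_filter(f, size=window, mode="nearest"),
                            window, mode="nearest")


def _raw_noise_sigma(f: np.ndarray) -> float:
    """Robust per-read noise scale from first differences of the raw trace:
    sigma = 1.4826 * MAD(diff f) / sqrt(2) (exact for iid Gaussian reads)."""
    d = np.diff(f)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def preprocess(trace: RawTrace, smooth_window: int = 5,
               baseline_quantile: float = 0.05,
               analysis_window: tuple[float, float] | None = None) -> ProcessedTrace:
    """Interpolate short dropouts and smooth a raw trace.

    The baseline recorded here is provisional (a low quantile of the whole
    analysis window); it is re-estimated over the pre-peak segment once the
    peak is known. Invalid traces (long missing-data runs) come back with
    ``valid=False`` and a MISSING_DATA flag instead of raising, so that a
    plate batch never aborts on one bad well.
    """
    FitParams(smooth_window=smooth_window, baseline_quantile=baseline_quantile)
    t = trace.grid.times
    window = (float(t[0]), float(t[-1])) if analysis_window is None else (
        float(analysis_window[0]), float(analysis_window[1]))
    if not (t[0] - 1e-9 <= window[0] < window[1] <= t[-1] + 1e-9):
        raise ConfigError(f"analysis window {window} outside grid span {trace.grid.span}")
    if not trace.valid:
        return ProcessedTrace(trace.well_id, trace.grid,
                              np.full_like(t, np.nan), np.nan, window,
                              valid=False, flags={MISSING_DATA})
    f_raw = _interpolate_gaps(trace.fluorescence, t)
    f_smooth = _smooth(f_raw, smooth_window)
    p = ProcessedTrace(trace.well_id, trace.grid, f_smooth, np.nan, window,
                       noise_sigma=_raw_noise_sigma(f_raw))
    sl = p.window_slice()
    p.baseline = float(np.quantile(f_smooth[sl], baseline_quantile))
    # saturated detector: many reads pinned at one ceiling value; exact
    # ties are only suspicious when the trace carries read noise
    seg = trace.fluorescence[sl]
    seg = seg[np.isfinite(seg)]
    if seg.size and p.noise_sigma > 0 and np.unique(seg).size > 1:
        if np.mean(seg == seg.max()) >= 0.05:
            p.flags.add(SATURATED)
    return p


# ---------------------------------------------------------------------------
# 2. peak detection


def detect_peak(p: ProcessedTrace, min_prominence_mads: float = 5.0) -> PeakCall:
    """Find the most prominent significant peak of the smoothed trace.

    Candidates are local maxima within the analysis window (boundary maxima
    included). A peak is significant iff its prominence is at least
    ``min_prominence_mads`` times the per-read noise scale and strictly
    positive. Ties in prominence go to the earliest peak. Absence of a
    significant peak is a result (``significant=False``), not an error.
    """
    sl = p.window_slice()
    f = p.f_smooth[sl]
    t = p.grid.times[sl]
    if not p.valid or not np.isfinite(f).all() or len(f) < 3:
        return PeakCall(np.nan, np.nan, 0.0, p.window, False)
    # min-value sentinels make boundary maxima detectable as peaks while
    # keeping their prominences finite (height above the trace minimum);
    # an all-flat trace yields no candidate at all
    padded = np.concatenate(([f.min()], f, [f.min()]))
    idx, props = find_peaks(padded, prominence=0)
    idx = idx - 1
    prom = props["prominences"]
    threshold = min_prominence_mads * p.noise_sigma
    keep = (prom >= threshold) & (prom > 0)
    if not keep.any():
        return PeakCall(np.nan, np.nan, float(prom.max(initial=0.0)), p.window, False)
    idx, prom = idx[keep], prom[keep]
    # greatest prominence; ties broken by earliest time
    best = np.lexsort((t[idx], -prom))[0]
    i = int(idx[best])
    return PeakCall(float(t[i]), float(f[i]), float(prom[best]), p.window, True)


def refine_baseline(p: ProcessedTrace, peak: PeakCall,
                    baseline_quantile: float = 0.05) -> ProcessedTrace:
    """Re-estimate the baseline as a low quantile of the smoothed signal
    before the detected peak (the pre-rise segment)."""
    sl = p.window_slice()
    t = p.grid.times[sl]
    f = p.f_smooth[sl]
    pre = f[t <= peak.t_peak]
    if pre.size == 0:
        return p
    return replace(p, baseline=float(np.quantile(pre, baseline_quantile)))


# ---------------------------------------------------------------------------
# 3. normalization


class DynamicRangeError(ValueError):
    """Peak does not rise above baseline; nothing to normalize."""


def normalize(p: ProcessedTrace, peak: PeakCall) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize the rising phase.

    Returns ``(t, g)`` restricted to [window start, t_peak] with
    ``g = clip((f_smooth - baseline) / (f_peak - baseline), 0, 1)``, so
    ``g`` is invariant under affine rescaling of the fluorescence.
    """
    if not peak.significant:
        raise ValueError("normalize requires a significant peak")
    if not peak.f_peak > p.baseline:
        raise DynamicRangeError(
            f"peak {peak.f_peak:g} does not exceed baseline {p.baseline:g}")
    sl = p.window_slice()
    t = p.grid.times[sl]
    f = p.f_smooth[sl]
    m = t <= peak.t_peak + 1e-9
    g = np.clip((f[m] - p.baseline) / (peak.f_peak - p.baseline), 0.0, 1.0)
    return t[m], g


# ---------------------------------------------------------------------------
# 4. half-max estimation


def _first_upcrossing(t: np.ndarray, g: np.ndarray, level: float) -> float | None:
    """Time of the first upward crossing of ``level``.

    Linear interpolation between the bracketing samples, with one special
    case: when the crossing jumps out of a flat plateau (two equal samples
    followed by a jump through the level), the crossing is attributed to
    the jump completion time. This is the right-continuous convention for
    step-like count traces, under which the half-maximum time of an
    instantaneous-burst trace equals the sample median of the death times.
    """
    above = g >= level
    if above[0]:
        # already above at window start: look for a later upward crossing
        below_seen = False
        for i in range(1, len(g)):
            if g[i] < level:
                below_seen = True
            elif below_seen:
                return _interp_cross(t, g, i, level)
        return None
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    return _interp_cross(t, g, int(idx[0]), level)


def _interp_cross(t, g, i, level) -> float:
    if g[i] == g[i - 1]:
        return float(t[i])
    if i >= 2 and g[i - 1] == g[i - 2]:
        # jump out of a flat plateau: step-function convention
        return float(t[i])
    return float(t[i - 1] + (level - g[i - 1]) / (g[i] - g[i - 1]) * (t[i] - t[i - 1]))


def _logistic(t, f0, a, t50, k):
    return f0 + a / (1.0 + np.exp(-np.clip(k * (t - t50), -500, 500)))


#: fraction of the normalized rise above which samples are excluded from
#: the sigmoid fit: near the peak the burst-decay process bends the curve
#: away from a logistic, so the fit covers baseline through 95% of the rise
RISE_CAP = 0.95


def _fit_logistic(t, f, g, baseline, f_peak, t50_init):
    """Bounded least-squares fit of the 4-parameter logistic to the rising
    phase (capped at RISE_CAP of the normalized rise).

    Returns (params dict, rmse, t_half) or raises on failure. ``t_half`` is
    the time at which the fitted curve crosses halfway between baseline and
    the observed peak — the same level manual curve reading interpolates —
    which for a well-fitted symmetric rise coincides with the midpoint t50.
    """
    a0 = max(f_peak - baseline, 1e-12)
    above = np.nonzero(g >= RISE_CAP)[0]
    if above.size:
        cap = max(int(above[0]) + 1, min(10, len(t)))
        t, f = t[:cap], f[:cap]
    p0 = [baseline, a0, t50_init, np.nan]
    # steepness init from the normalized quartile crossing times
    t25 = _first_upcrossing(t, np.clip((f - baseline) / a0, 0, 1), 0.25)
    t75 = _first_upcrossing(t, np.clip((f - baseline) / a0, 0, 1), 0.75)
    cad = float(np.median(np.diff(t)))
    p0[3] = 4.0 / (t75 - t25) if (t25 is not None and t75 is not None
                                  and t75 > t25) else 1.0 / cad
    # identifiability on a partial sigmoid: the plateau F0 + A must land
    # near the observed peak, F0 near the baseline, and the midpoint
    # cannot leave the window
    lo = [min(0.0, baseline - 0.25 * a0), 0.5 * a0, t[0], 1e-3]
    hi = [baseline + 0.25 * a0, 1.3 * a0, t[-1], 10.0 / cad]
    p0 = np.clip(p0, lo, hi)
    popt, _ = curve_fit(_logistic, t, f, p0=p0, bounds=(lo, hi), maxfev=5000)
    f0, a, t50, k = (float(v) for v in popt)
    resid = _logistic(t, *popt) - f
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    level = baseline + 0.5 * a0
    if f0 < level < f0 + a:
        t_half = t50 - np.log(a / (level - f0) - 1.0) / k
    else:
        t_half = t50
    return {"F0": f0, "A": a, "t50": t50, "k": k}, rmse, float(t_half)


def fit_half_max(p: ProcessedTrace, peak: PeakCall, mode: str = "auto",
                 params: FitParams | None = None) -> FitResult:
    """Estimate the median time of death of one well.

    ``auto`` fits ``F0 + A / (1 + exp(-k (t - t50)))`` to the rising phase
    by bounded least squares and reports the time at which the fitted
    curve crosses the half-maximum level (equal to the midpoint ``t50``
    whenever the fitted plateau matches the observed peak);
    it falls back to the interpolation estimate (flag FALLBACK_INTERP,
    status REVIEW) when the optimizer fails or the relative residual
    ``rmse/A`` exceeds the review threshold. ``interpolation`` reproduces
    manual curve reading: the first upward half-maximum crossing of the
    normalized trace.
    """
    params = params or FitParams()
    if mode not in ("auto", "interpolation"):
        raise ConfigError(f"unknown fit mode {mode!r}")
    fr = FitResult(well_id=p.well_id, flags=set(p.flags))
    if not p.valid:
        fr.flags.add(MISSING_DATA)
        return fr
    if not peak.significant:
        fr.flags.add(NO_SIGNIFICANT_PEAK)
        return fr
    fr.t_peak = peak.t_peak
    fr.peak_prominence = peak.prominence
    try:
        t, g = normalize(p, peak)
    except DynamicRangeError:
        fr.flags.add(NO_DYNAMIC_RANGE)
        return fr
    t_interp = _first_upcrossing(t, g, 0.5)
    if t_interp is None:
        fr.flags.add(NO_HALF_CROSSING)
        return fr
    fr.params = {"F0": p.baseline, "A": peak.f_peak - p.baseline,
                 "t50": t_interp, "k": float("nan")}
    fr.method = "interpolation"
    fr.t_half = t_interp
    fr.status = STATUS_OK
    if mode == "auto":
        sl = p.window_slice()
        rise = p.f_smooth[sl][p.grid.times[sl] <= peak.t_peak + 1e-9]
        try:
            fitted, rmse, t_half = _fit_logistic(t, rise, g, p.baseline,
                                                 peak.f_peak, t_interp)
            fr.rmse = rmse
            if rmse / fitted["A"] > params.rmse_review:
                fr.flags.add(FALLBACK_INTERP)
                fr.flags.add(HIGH_RMSE)
                fr.diagnostics["sigmoid_t50"] = fitted["t50"]
            else:
                fr.method = "sigmoid_fit"
                fr.params = fitted
                fr.t_half = t_half
        except (RuntimeError, ValueError, OptimizeWarning):
            fr.flags.add(FALLBACK_INTERP)
    return classify_fit(fr, p, params)


# ---------------------------------------------------------------------------
# 5. QC classification


def classify_fit(fit: FitResult, p: ProcessedTrace | None = None,
                 params: FitParams | None = None) -> FitResult:
    """Assign the final QC status.

    UNFIT: no significant peak, no half crossing, missing data, estimate
    outside [first read + cadence, last read - cadence], or relative
    residual above ``rmse_unfit``. REVIEW: interpolation fallback was used,
    the residual is borderline, or the detector looks saturated. OK
    otherwise. UNFIT wells report no ``t_half``.
    """
    params = params or FitParams()
    hard = {MISSING_DATA, NO_SIGNIFICANT_PEAK, NO_DYNAMIC_RANGE, NO_HALF_CROSSING}
    if fit.flags & hard or fit.t_half is None:
        _mark_unfit(fit)
        return fit
    if p is not None:
        t = p.grid.times
        cad = p.grid.nominal_cadence
        lo, hi = max(t[0], p.window[0]) + cad, min(t[-1], p.window[1]) - cad
        if not (lo <= fit.t_half <= hi):
            fit.flags.add(OUT_OF_WINDOW)
            _mark_unfit(fit)
            return fit
    a = fit.params.get("A", float("nan"))
    rel = fit.rmse / a if (np.isfinite(fit.rmse) and a and np.isfinite(a)) else float("nan")
    if np.isfinite(rel) and rel > params.rmse_unfit:
        fit.flags.add(HIGH_RMSE)
        _mark_unfit(fit)
        return fit
    if (FALLBACK_INTERP in fit.flags or SATURATED in fit.flags
            or (np.isfinite(rel) and rel > params.rmse_review)):
        fit.status = STATUS_REVIEW
        if np.isfinite(rel) and rel > params.rmse_review:
            fit.flags.add(HIGH_RMSE)
    else:
        fit.status = STATUS_OK
    return fit


def _mark_unfit(fit: FitResult) -> None:
    if fit.t_half is not None:
        fit.diagnostics["t_half_raw"] = fit.t_half
    fit.t_half = None
    fit.status = STATUS_UNFIT


# ---------------------------------------------------------------------------
# batch


def batch_fit(run: PlateRun, params: FitParams | None = None,
              mode: str = "auto") -> list[FitResult]:
    """Fit every well of a run; one :class:`FitResult` per trace, in
    row-major well order. Well-level failures become statuses, never
    exceptions, and identical inputs give identical results."""
    params = params or FitParams()
    results = []
    for trace in run.traces:
        p = preprocess(trace, params.smooth_window, params.baseline_quantile,
                       params.analysis_window)
        peak = detect_peak(p, params.min_prominence_mads)
        if peak.significant:
            p = refine_baseline(p, peak, params.baseline_quantile)
        fr = fit_half_max(p, peak, mode=mode, params=params)
        log.debug("well %s: status=%s t_half=%s flags=%s", trace.well_id,
                  fr.status, f"{fr.t_half:.2f}" if fr.t_half is not None else "-",
                  ",".join(sorted(fr.flags)) or "-")
        results.append(fr)
    counts = {s: sum(f.status == s for f in results)
              for s in (STATUS_OK, STATUS_REVIEW, STATUS_UNFIT)}
    log.info("batch_fit: %d wells, OK=%d REVIEW=%d UNFIT=%d", len(results),
             counts[STATUS_OK], counts[STATUS_REVIEW], counts[STATUS_UNFIT])
    return results


def review_queue(fits: Iterable[FitResult]) -> list[FitResult]:
    """Wells needing human re-analysis (REVIEW or UNFIT)."""
    return [f for f in fits if f.status in (STATUS_REVIEW, STATUS_UNFIT)]
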
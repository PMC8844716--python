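"""Single-cell fluorescence time-series analysis.

Pipeline, in the order it is applied to each cell's intensity trace
(60 samples on a 2-min grid by default):

1. imputation of missing frames (a lone missing point becomes the mean of
   up to three observed neighbours on each side; runs of missing points are
   linearly interpolated),
2. moving-average noise filtering with symmetric window half-width n
   (default 8) and boundary truncation,
3. cubic-spline interpolation of the filtered series (not-a-knot ends) for
   continuous evaluation,
4. removal of the mean and of an ordinary-least-squares linear growth
   trend, isolating the oscillatory component,
5. period estimation from the autocorrelation of the de-trended series,
6. Takens time-delay embedding (x_t against x_{t+k}) whose closed loop is
   the signature of a periodic limit cycle,
7. rule-based classification of each cell as absent / decreasing /
   constant / oscillating, and a population tally with percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.signal.windows import tukey

CATEGORIES = ("absent", "decreasing", "constant", "oscillating")


@dataclass(frozen=True)
class FluorescenceTrace:
    """One cell's intensity series on a uniform time grid.

    ``intensities`` holds NaN at masked (missing) frames; ``missing`` is the
    boolean mask.  Intensities are arbitrary fluorescence units.
    """

    cell_id: str
    times: np.ndarray
    intensities: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]
    category: str | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        vals = np.asarray(self.intensities, dtype=float)
        if self.missing is None:
            mask = np.isnan(vals)
        else:
            mask = np.asarray(self.missing, dtype=bool)
        if times.shape != vals.shape or mask.shape != vals.shape:
            raise ValueError("times, intensities and mask must share a shape")
        d = np.diff(times)
        if len(times) >= 2 and (d <= 0).any():
            raise ValueError("times must be strictly increasing")
        if len(times) >= 3 and not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        vals = vals.copy()
        vals[mask] = np.nan
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", vals)
        object.__setattr__(self, "missing", mask)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return len(self.times)


def impute_missing(trace: FluorescenceTrace,
                   max_missing_fraction: float = 0.2) -> FluorescenceTrace:
    """Fill masked frames.

    A lone missing point is replaced by the mean of up to three observed
    values before and three after it.  Runs of two or more consecutive
    missing points are filled by linear interpolation between the flanking
    observed values; missing points at either end take the nearest observed
    value.  More than ``max_missing_fraction`` missing is rejected.
    """
    mask = trace.missing
    if not mask.any():
        return trace
    n = trace.n_samples
    if mask.sum() > max_missing_fraction * n:
        raise ValueError(
            f"{int(mask.sum())}/{n} points missing exceeds the "
            f"{max_missing_fraction:.0%} limit"
        )
    if mask.all():
        raise ValueError("no observed points to impute from")
    x = trace.intensities.copy()
    obs_idx = np.flatnonzero(~mask)
    filled = x.copy()
    for i in np.flatnonzero(mask):
        isolated = (i == 0 or not mask[i - 1]) and (i == n - 1 or not mask[i + 1])
        if isolated:
            before = obs_idx[obs_idx < i][-3:]
            after = obs_idx[obs_idx > i][:3]
            neigh = np.concatenate([before, after])
            filled[i] = x[neigh].mean()
        else:
            # part of a run: linear interpolation (constant extension at ends)
            filled[i] = np.interp(trace.times[i], trace.times[obs_idx], x[obs_idx])
    return replace(trace, intensities=filled,
                   missing=np.zeros(n, dtype=bool))


def moving_average(series: Sequence[float], n: int = 8) -> np.ndarray:
    """Symmetric moving-average filter with boundary truncation.

    y_k is the mean of x over indices [k-n, k+n] clipped to the series;
    out-of-bounds indices are simply dropped from the average (the window
    sum divides by however many points it actually covers).  n = 0 is the
    identity.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty series")
    if n < 0:
        raise ValueError("window half-width must be >= 0")
    if n == 0:
        return x.copy()
    kernel = np.ones(2 * n + 1)
    # full convolution with an explicit centre slice: mode="same" mis-sizes
    # the output when the window is longer than the series
    sums = np.convolve(x, kernel, mode="full")[n: n + x.size]
    counts = np.convolve(np.ones_like(x), kernel, mode="full")[n: n + x.size]
    return sums / counts


def fit_spline(times: Sequence[float], values: Sequence[float]) -> CubicSpline:
    """Interpolating cubic spline through (times, values), not-a-knot ends."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("spline fitting needs at least 4 points")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing (no duplicates)")
    return CubicSpline(t, y, bc_type="not-a-knot")


def eval_spline(spline: CubicSpline, query_times: Sequence[float]) -> np.ndarray:
    return np.asarray(spline(np.asarray(query_times, dtype=float)))


def fit_linear_trend(times: Sequence[float], values: Sequence[float]):
    """Ordinary least squares line y = m*t + c; returns (m, c)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points to fit a line")
    if np.ptp(t) == 0:
        raise ValueError("all times identical; slope undefined")
    m, c = np.polyfit(t, y, 1)
    return float(m), float(c)


def detrend(values: Sequence[float], times: Sequence[float]) -> np.ndarray:
    """Remove the mean, then the OLS linear growth trend.

    The returned series has zero mean and zero OLS slope (to numerical
    tolerance), leaving only fluctuations about the linear growth.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points to de-trend")
    z = y - y.mean()
    m, c = fit_linear_trend(t, z)
    return z - (m * t + c)


def estimate_period(times: Sequence[float], detrended: Sequence[float],
                    min_correlation: float = 0.2,
                    taper_fraction: float = 0.25) -> float | None:
    """Dominant period (min) of a de-trended series, or None.

    The series is tapered with a Tukey window (cosine-rolled outer
    ``taper_fraction`` of samples — standard practice for sample
    autocorrelations of short records, and the region a truncated
    moving-average window distorts most); the autocorrelation is then
    scanned past its first non-positive lag, the maximising lag refined by
    parabolic interpolation through its neighbours and converted to
    minutes.  If the autocorrelation never crosses zero the mean spacing of
    prominent peaks in the series is used instead.  A maximum
    autocorrelation below ``min_correlation`` (or a featureless series)
    yields None rather than an estimate.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(detrended, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points to estimate a period")
    dt = t[1] - t[0]
    x = x - x.mean()
    if taper_fraction > 0:
        x = x * tukey(x.size, taper_fraction)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return None
    acf = np.correlate(x, x, mode="full")[x.size - 1:] / denom
    max_lag = (3 * x.size) // 4  # longer lags average too few samples
    crossings = np.flatnonzero(acf[: max_lag + 1] <= 0)
    if crossings.size == 0:
        return _peak_spacing_period(t, x)
    start = int(crossings[0])
    seg = acf[start: max_lag + 1]
    if seg.size == 0:
        return None
    lag = start + int(np.argmax(seg))
    if acf[lag] < min_correlation:
        return None
    # parabolic sub-sample refinement through the three points around the peak
    if 1 <= lag < len(acf) - 1:
        y0, y1, y2 = acf[lag - 1], acf[lag], acf[lag + 1]
        denom2 = y0 - 2 * y1 + y2
        if denom2 != 0:
            lag = lag + 0.5 * (y0 - y2) / denom2
    return float(lag * dt)


def _peak_spacing_period(t: np.ndarray, x: np.ndarray) -> float | None:
    prominence = 0.1 * np.ptp(x) if np.ptp(x) > 0 else None
    peaks, _ = find_peaks(x, prominence=prominence)
    if len(peaks) < 2:
        return None
    return float(np.mean(np.diff(t[peaks])))


def embed_phase_space(series: Sequence[float], k: int) -> np.ndarray:
    """Takens delay embedding: the N-k ordered pairs (x_i, x_{i+k})."""
    x = np.asarray(series, dtype=float)
    if not 0 < k < x.size:
        raise ValueError(f"delay k={k} must satisfy 0 < k < {x.size}")
    return np.column_stack([x[: x.size - k], x[k:]])


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds operationalising the by-eye phenotype calls.

    theta_abs    absolute intensity floor below which a cell is 'absent'
                 (units of the trace; default 20 against a ~100-unit
                 baseline signal),
    theta_prom   prominence a peak/trough must reach, as a fraction of the
                 filtered range, for the rise-fall-rise test,
    theta_slope  fractional decline (OLS slope x duration / range) beyond
                 which a non-oscillating cell is 'decreasing',
    theta_range  minimum filtered range relative to the mean signal for the
                 oscillation test (guards near-flat traces whose noise
                 wiggles would pass a purely relative prominence test),
    window       moving-average half-width used for the filtered series.
    """

    theta_abs: float = 25.0
    theta_prom: float = 0.15
    theta_slope: float = 0.5
    theta_range: float = 0.1
    window: int = 8


def classify_trace(trace: FluorescenceTrace,
                   params: ClassifierParams | None = None) -> str:
    """Assign one of absent / decreasing / constant / oscillating."""
    params = params or ClassifierParams()
    trace = impute_missing(trace)
    x = trace.intensities
    if np.nanmax(x) < params.theta_abs:
        return "absent"
    f = moving_average(x, params.window)
    # peak detection runs on the de-trended filtered series: removing the
    # linear growth restores extrema the trend would otherwise swallow.
    # Prominence is measured against the filtered range, so small wiggles on
    # a large monotone signal do not count as cycles.
    d = detrend(f, trace.times)
    rng_d = float(np.ptp(d))
    rng_f = float(np.ptp(f))
    prom = params.theta_prom * rng_f if rng_f > 0 else None
    peaks, _ = find_peaks(d, prominence=prom)
    troughs, _ = find_peaks(-d, prominence=prom)
    # one full cycle = three alternating extrema of either polarity
    # (max-min-max, or min-max-min when the maxima fall at the record ends)
    has_cycle = (
        len(peaks) >= 2 and any(peaks[0] < tr < peaks[-1] for tr in troughs)
    ) or (
        len(troughs) >= 2 and any(troughs[0] < pk < troughs[-1] for pk in peaks)
    )
    scale = max(float(np.mean(f)), 1e-12)
    if has_cycle and rng_d >= params.theta_range * scale:
        return "oscillating"
    m, _ = fit_linear_trend(trace.times, f)
    rng_f = float(np.ptp(f))
    duration = float(trace.times[-1] - trace.times[0])
    if rng_f > 0 and m * duration < -params.theta_slope * rng_f:
        return "decreasing"
    return "constant"


@dataclass(frozen=True)
class PopulationSummary:
    """Per-category cell counts and 1-decimal percentages."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def summarize_population(categories: Sequence[str]) -> PopulationSummary:
    """Tally categories and express each as a percentage of all cells."""
    cats = list(categories)
    if not cats:
        raise ValueError("no categories to summarise")
    counts = {c: cats.count(c) for c in CATEGORIES}
    extra = sorted(set(cats) - set(CATEGORIES))
    if extra:
        raise ValueError(f"unknown categories {extra}")
    total = len(cats)
    percentages = {c: round(100.0 * n / total, 1) for c, n in counts.items()}
    return PopulationSummary(counts=counts, percentages=percentages, total=total)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the per-cell pipeline produces."""

    trace: FluorescenceTrace
    imputed: np.ndarray
    filtered: np.ndarray
    spline: CubicSpline
    trend_slope: float          # units/min, OLS fit to the filtered series
    trend_intercept: float      # units
    detrended: np.ndarray
    period: float | None        # minutes, None when no periodicity is found
    delay_k: int                # embedding delay in samples
    phase_pairs: np.ndarray     # (N - k, 2)
    category: str


def analyze_trace(trace: FluorescenceTrace, window: int = 8,
                  delay: int | str = "auto",
                  classifier_params: ClassifierParams | None = None
                  ) -> AnalysisResult:
    """Run the full pipeline on one trace.

    ``delay='auto'`` sets the embedding delay to a quarter of the estimated
    period (in samples, rounded); when no period is found a quarter of the
    record length is used so the embedding is still produced.
    """
    imputed_trace = impute_missing(trace)
    imputed = imputed_trace.intensities
    filtered = moving_average(imputed, window)
    spline = fit_spline(trace.times, filtered)
    m, c = fit_linear_trend(trace.times, filtered)
    det = detrend(filtered, trace.times)
    period = estimate_period(trace.times, det)
    dt = trace.dt
    if delay == "auto":
        if period is not None:
            k = max(1, int(round(period / 4.0 / dt)))
        else:
            k = max(1, trace.n_samples // 4)
        k = min(k, trace.n_samples - 1)
    else:
        k = int(delay)
    pairs = embed_phase_space(det, k)
    category = classify_trace(
        trace, classifier_params or ClassifierParams(window=window)
    )
    return AnalysisResult(
        trace=trace, imputed=imputed, filtered=filtered, spline=spline,
        trend_slope=m, trend_intercept=c, detrended=det, period=period,
        delay_k=k, phase_pairs=pairs, category=category,
    )
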
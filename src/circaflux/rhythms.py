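"""Detrending and circadian parameter estimation for luminescence traces.

Baseline subtraction by a centered running average, damped-sine period
fitting (y = A * exp(-t/tau) * sin(2*pi*t/T + phi) + offset) initialized
from the periodogram, peak detection with sub-sample refinement,
peak-to-peak phase shifts between conditions, circular acrophase summaries
for polar plots, and the 2^-ddCt qPCR fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .core import InvalidInputError, TraceSet

DEFAULT_PERIOD_BOUNDS_H = (16.0, 32.0)


# ---------------------------------------------------------------------------
# baseline subtraction
# ---------------------------------------------------------------------------

def _running_baseline(y: np.ndarray, dt_h: float, window_h: float) -> np.ndarray:
    # Trapezoid-weighted centered mean over a window of width exactly
    # window_h: half weight at both endpoints.  Symmetric, so linear trends
    # are removed exactly; a closed trapezoid over a whole number of periods
    # of any sinusoid is exactly zero, so in-band oscillations pass through
    # untouched in the interior.  Edges fall back to the shrinking
    # (normalized) version of the same window.
    n_half = int(round(window_h / (2.0 * dt_h)))
    if n_half < 1:
        raise InvalidInputError("window_h must exceed the sampling interval")
    w = np.ones(2 * n_half + 1)
    w[0] = w[-1] = 0.5
    num = _centered_sum(y, w)
    den = _centered_sum(np.ones_like(y), w)
    return num / den


def _centered_sum(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    # zero padding + renormalization by the same kernel = shrinking windows
    return np.convolve(y, w[::-1], mode="same")


def detrend_running(ts: TraceSet, window_h: float = 24.0) -> TraceSet:
    """Subtract a centered running-average baseline of width ``window_h``."""
    if window_h <= 0:
        raise InvalidInputError("window_h must be positive")
    span = ts.time_h[-1] - ts.time_h[0]
    if window_h >= span:
        raise InvalidInputError("window_h must be shorter than the trace")
    out = np.empty_like(ts.values)
    for j in range(ts.n_traces):
        out[:, j] = ts.values[:, j] - _running_baseline(ts.values[:, j],
                                                        ts.dt_h, window_h)
    return ts.with_values(out)


def detrend_window24(ts: TraceSet) -> TraceSet:
    """Baseline from a centered 24-h moving window (the expected period)."""
    return detrend_running(ts, window_h=24.0)


# ---------------------------------------------------------------------------
# damped-sine fitting
# ---------------------------------------------------------------------------

@dataclass
class DampedSineFit:
    """Damped-sinusoid fit y = A*exp(-t/tau)*sin(2*pi*t/T + phi) + offset."""

    amplitude: float
    damping_tau_h: float
    period_h: float
    phase_rad: float
    offset: float
    rmse: float
    converged: bool
    message: str = ""


def _periodogram_period_peaks(t: np.ndarray, y: np.ndarray,
                              bounds: tuple[float, float],
                              n_peaks: int = 3) -> list[float]:
    dt = float(np.median(np.diff(t)))
    freqs, power = signal.periodogram(y - y.mean(), fs=1.0 / dt,
                                      nfft=max(4096, 8 * t.size))
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    # genuine spectral peaks only: local maxima carrying a non-negligible
    # share of the dominant power (rejects sidelobe leakage of an
    # out-of-band oscillation)
    peak_idx, _ = signal.find_peaks(power)
    if peak_idx.size == 0 or power.max() <= 0:
        return []
    floor = 0.05 * float(power[peak_idx].max())
    in_band = peak_idx[(periods[peak_idx] >= bounds[0])
                       & (periods[peak_idx] <= bounds[1])
                       & (power[peak_idx] >= floor)]
    if in_band.size == 0:
        return []
    order = in_band[np.argsort(power[in_band])[::-1]]
    peaks: list[float] = []
    for i in order:
        p = float(periods[i])
        if all(abs(p - q) > 0.5 for q in peaks):
            peaks.append(p)
        if len(peaks) >= n_peaks:
            break
    return peaks


def _failed_fit(message: str) -> DampedSineFit:
    return DampedSineFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                         math.nan, False, message)


def fit_damped_sine(t: np.ndarray, y: np.ndarray,
                    period_bounds_h: tuple[float, float] = DEFAULT_PERIOD_BOUNDS_H,
                    ) -> DampedSineFit:
    """Nonlinear least-squares damped-sine fit of a detrended trace.

    The period is initialized from up to three periodogram peaks inside
    ``period_bounds_h`` (multi-start avoids locking onto harmonics); the
    damping is parameterized by its rate so an undamped fit (tau = inf) is
    on the boundary rather than at infinity.  Failure to find an in-band
    periodogram peak or to converge yields a flagged result, not an
    exception.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise InvalidInputError("t and y must have equal length")
    span = t[-1] - t[0]
    if span < 2.0 * period_bounds_h[0]:
        return _failed_fit("less than two putative cycles of data")
    period_inits = _periodogram_period_peaks(t, y, period_bounds_h)
    if not period_inits:
        return _failed_fit("no periodogram peak within period bounds")

    def residuals(x: np.ndarray) -> np.ndarray:
        amp, rate, period, phi, off = x
        return amp * np.exp(-rate * t) * np.sin(2 * np.pi * t / period + phi) + off - y

    best = None
    for period0 in period_inits:
        off0 = float(y.mean())
        yc = y - off0
        omega = 2 * np.pi / period0
        # linear projection gives amplitude and phase starts
        s_basis, c_basis = np.sin(omega * t), np.cos(omega * t)
        a = 2.0 * float(yc @ s_basis) / t.size
        b = 2.0 * float(yc @ c_basis) / t.size
        amp0 = max(math.hypot(a, b), 1e-12)
        phi0 = math.atan2(b, a)
        half = t.size // 2
        s1 = float(np.std(yc[:half])) + 1e-12
        s2 = float(np.std(yc[half:])) + 1e-12
        rate0 = max(0.0, 2.0 * math.log(s1 / s2) / span)
        x0 = np.array([amp0, rate0, period0, phi0, off0])
        lower = [0.0, 0.0, period_bounds_h[0], -2 * np.pi, -np.inf]
        upper = [np.inf, 1.0, period_bounds_h[1], 2 * np.pi, np.inf]
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lower, upper),
                                         method="trf", xtol=1e-12, ftol=1e-12,
                                         gtol=1e-12)
        except Exception:  # pragma: no cover - optimizer internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return _failed_fit("optimizer did not converge")
    amp, rate, period, phi, off = best.x
    tau = math.inf if rate <= 1e-12 else 1.0 / rate
    phi = math.remainder(phi, 2 * math.pi)  # wrap to (-pi, pi]
    rmse = float(np.sqrt(2.0 * best.cost / t.size))
    return DampedSineFit(float(amp), tau, float(period), float(phi),
                         float(off), rmse, True)


def fit_traces(ts: TraceSet,
               period_bounds_h: tuple[float, float] = DEFAULT_PERIOD_BOUNDS_H,
               ) -> dict[str, DampedSineFit]:
    """Fit every trace of a detrended TraceSet; keyed by trace name."""
    return {name: fit_damped_sine(ts.time_h, ts.trace(name), period_bounds_h)
            for name in ts.names}


# ---------------------------------------------------------------------------
# peaks and phase shifts
# ---------------------------------------------------------------------------

def detect_peaks(t: np.ndarray, y: np.ndarray,
                 min_separation_h: float = 12.0,
                 smooth_window_h: float | None = None,
                 interpolate: bool = True,
                 min_prominence_frac: float = 0.05) -> np.ndarray:
    """Times (h) of local maxima separated by at least ``min_separation_h``.

    Peaks must rise at least ``min_prominence_frac`` of the trace's range
    above their surroundings (rejects noise bumps near troughs), and their
    times are refined by quadratic interpolation of the three samples
    around each maximum (``interpolate=False`` keeps the raw sample times,
    i.e. sampling-interval resolution).
    """
    if min_separation_h <= 0:
        raise InvalidInputError("min_separation_h must be positive")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = float(np.median(np.diff(t)))
    if smooth_window_h:
        n = max(1, int(round(smooth_window_h / dt)))
        y = np.convolve(y, np.ones(n) / n, mode="same")
    distance = max(1, int(round(min_separation_h / dt)))
    prominence = min_prominence_frac * float(np.ptp(y)) if np.ptp(y) > 0 else None
    idx, _ = signal.find_peaks(y, distance=distance, prominence=prominence)
    times = []
    for i in idx:
        if interpolate and 0 < i < t.size - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            times.append(t[i] + float(np.clip(delta, -1, 1)) * dt)
        else:
            times.append(t[i])
    return np.asarray(times)


def peak_phase_shift(peaks_a: np.ndarray, peaks_b: np.ndarray,
                     period_h: float = 24.0) -> float:
    """Signed mean peak-to-peak time difference between two conditions.

    Peaks are paired by mutual nearest neighbor within half a period, which
    makes the statistic exactly antisymmetric under argument swap.  A
    positive value means condition A peaks later than B.  Returns NaN when
    no peaks pair up (flagged failure).
    """
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both peak lists must be non-empty")
    diffs = []
    for i, ta in enumerate(a):
        j = int(np.argmin(np.abs(b - ta)))
        if abs(b[j] - ta) > period_h / 2.0:
            continue
        i_back = int(np.argmin(np.abs(a - b[j])))
        if i_back == i:  # mutual nearest neighbors only
            diffs.append(ta - b[j])
    if not diffs:
        return math.nan
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# circular acrophase statistics
# ---------------------------------------------------------------------------

@dataclass
class AcrophaseSummary:
    """Polar summary of acrophases on the 24-h circle."""

    mean_acrophase_h: float   # circular mean, in [0, 24)
    circular_sd_h: float      # sqrt(-2 ln Rbar) mapped to hours
    mean_amplitude: float
    n: int


def acrophase_polar(acrophases_h: np.ndarray,
                    amplitudes: np.ndarray | None = None) -> AcrophaseSummary:
    """Circular mean/SD of acrophases (hours mod 24) with mean amplitude.

    Angles are 2*pi*h/24; the circular SD is sqrt(-2 ln Rbar) converted
    back to hours, the standard directional-statistics definition.
    """
    a = np.asarray(acrophases_h, dtype=float)
    if a.size == 0:
        raise InvalidInputError("need at least one acrophase")
    ang = 2 * np.pi * a / 24.0
    z = np.exp(1j * ang).mean()
    rbar = min(float(np.abs(z)), 1.0)
    mean_h = round(float(np.angle(z)) * 24.0 / (2 * np.pi), 12) % 24.0
    sd_h = math.sqrt(max(-2.0 * math.log(max(rbar, 1e-300)), 0.0)) * 24.0 / (2 * np.pi)
    mean_amp = float(np.mean(amplitudes)) if amplitudes is not None else math.nan
    return AcrophaseSummary(mean_h, sd_h, mean_amp, int(a.size))


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def fold_change_ddct(ct_gene: float, ct_ref: float,
                     ct_gene_cal: float, ct_ref_cal: float) -> float:
    """Relative qPCR fold change by the 2^-ddCt method.

    dCt = Ct(gene) - Ct(reference); ddCt subtracts the calibrator sample's
    dCt; the fold change is 2**(-ddCt).
    """
    for v in (ct_gene, ct_ref, ct_gene_cal, ct_ref_cal):
        if not math.isfinite(v):
            raise InvalidInputError("Ct values must be finite")
    ddct = (ct_gene - ct_ref) - (ct_gene_cal - ct_ref_cal)
    return 2.0 ** (-ddct)
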
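"""Chamber-level and single-cell trace statistics.

Implements the full analysis stack for fluorescence time series recorded from
paired growth chambers: smoothing and normalization, growth inference from
reporter dilution, oscillation peak statistics, Welch spectra and
signal-to-noise ratios, bootstrap resampling and hypothesis tests,
cross-correlation and phase-drift metrics, robust outlier screening, and
single-cell growth rates.

Sampling is on a uniform grid (7 min for quorum-sensing experiments, 10 min
for auxotroph experiments).  All stochastic routines take an explicit numpy
Generator or seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "ChamberTrace",
    "OscillationSummary",
    "SpectrumSummary",
    "moving_mean",
    "normalize_oscillator_trace",
    "global_normalization_constants",
    "delta_f_rate",
    "doubling_time",
    "biphasic_peaks",
    "detect_peaks",
    "oscillation_amplitude",
    "welch_spectrum",
    "snr",
    "bootstrap_snr",
    "bootstrap_mean_test",
    "bootstrap_curves",
    "max_cross_correlation",
    "phase_drift_cv",
    "modified_zscore",
    "modified_zscore_outliers",
    "single_cell_growth_rate",
    "partner_abundance_correlation",
]

#: Default Methods thresholds.
OSCILLATOR_MIN_PEAK_DISTANCE_MIN = 70.0
OSCILLATOR_MIN_PEAK_HEIGHT = 0.015
FORCED_MIN_PEAK_DISTANCE_MIN = 21.0
MOVING_MEAN_POINTS = 20
SLOPE_WINDOW_POINTS = 10
OUTLIER_THRESHOLD = 3.5
SIGNAL_BAND_HALF_WIDTH_MIN = 10.0
SINGLE_CELL_WINDOW_MIN = 100.0
BOOTSTRAP_B = 10_000


@dataclass
class ChamberTrace:
    """One chamber's reporter time series with its metadata."""

    time_min: np.ndarray
    values: np.ndarray
    chamber_id: str
    channel_length_um: float
    reporter: str
    replicate: int = 0
    strain: str | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_min.shape != self.values.shape:
            raise ValueError("time and value arrays must match")
        if self.time_min.size >= 2:
            dt = np.diff(self.time_min)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])


@dataclass
class OscillationSummary:
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    interpeak_cv: float

    @property
    def n_peaks(self) -> int:
        return int(len(self.peak_times))


@dataclass
class SpectrumSummary:
    frequencies: np.ndarray          # per min
    power: np.ndarray                # AU^2 * min
    signal_band: tuple[float, float] | None = None

    def band_from_period(self, period_min: float,
                         half_width_min: float = SIGNAL_BAND_HALF_WIDTH_MIN) -> None:
        """Set the signal band to +/- ``half_width_min`` around the input
        period, converted to a frequency interval [1/(T+w), 1/(T-w)]."""
        if period_min <= half_width_min:
            raise ValueError("period must exceed the band half-width")
        self.signal_band = (1.0 / (period_min + half_width_min),
                            1.0 / (period_min - half_width_min))


def moving_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows shrink symmetrically at the edges."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > values.size:
        raise ValueError("window longer than the series")
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def global_normalization_constants(traces: Sequence[np.ndarray]) -> tuple[float, float]:
    """(global minimum, global post-subtraction maximum) across replicates."""
    gmin = min(float(np.min(t)) for t in traces)
    gmax = max(float(np.max(t)) for t in traces) - gmin
    return gmin, gmax


def normalize_oscillator_trace(values: np.ndarray, global_min: float,
                               global_max: float,
                               smooth_points: int = MOVING_MEAN_POINTS) -> np.ndarray:
    """Reporter normalization for oscillator traces.

    Subtract the global minimum across replicates, divide by the global
    maximum, then smooth with a 20-point moving mean.
    """
    if global_max <= 0:
        raise ValueError("degenerate global range (max <= 0 after min subtraction)")
    scaled = (np.asarray(values, dtype=float) - global_min) / global_max
    return moving_mean(scaled, min(smooth_points, scaled.size))


def delta_f_rate(values: np.ndarray, dt_min: float,
                 window: int = SLOPE_WINDOW_POINTS) -> np.ndarray:
    """Reporter-dilution growth signal: minus the windowed slope of the trace.

    A least-squares line is fitted to each ``window``-point moving window of
    the background-subtracted, max-normalized trace; the slope times -1 is the
    per-minute dilution rate, positive while growth dilutes the reporter.
    The i-th output corresponds to the window starting at sample i.
    """
    values = np.asarray(values, dtype=float)
    if values.size < window:
        raise ValueError(f"need at least {window} points")
    t = np.arange(window) * dt_min
    t_c = t - t.mean()
    denom = float(np.dot(t_c, t_c))
    win = np.lib.stride_tricks.sliding_window_view(values, window)
    slopes = (win - win.mean(axis=1, keepdims=True)) @ t_c / denom
    return -slopes


def doubling_time(rate_series: np.ndarray) -> float:
    """ln(2) over the maximum dilution rate; ``inf`` if growth never positive."""
    rate_series = np.asarray(rate_series, dtype=float)
    peak = float(np.max(rate_series))
    if peak <= 0:
        return float("inf")
    return float(np.log(2) / peak)


@dataclass
class BiphasicResult:
    gp1_rate: float
    gp1_time_min: float
    gp2_rate: float | None
    gp2_time_min: float | None

    @property
    def biphasic(self) -> bool:
        return self.gp2_rate is not None


def biphasic_peaks(rate_series: np.ndarray, rate_times_min: np.ndarray,
                   trace: np.ndarray, trace_times_min: np.ndarray,
                   media_switch_min: float) -> BiphasicResult:
    """Growth-phase rates for dilution curves with two growth modes.

    The analysis window runs from the media switch to the time at which the
    (max-normalized) trace has fallen to 25% of its maximum.  GP1 is the
    global maximum of the dilution rate in that window; GP2 is the largest
    local maximum after GP1, up to the 25%-fluorescence time.  A curve with
    no later local maximum is reported single-phase.
    """
    rate_series = np.asarray(rate_series, float)
    rate_times_min = np.asarray(rate_times_min, float)
    trace = np.asarray(trace, float)
    trace_times_min = np.asarray(trace_times_min, float)
    fmax = float(np.max(trace))
    after_peak = trace_times_min >= trace_times_min[int(np.argmax(trace))]
    below = after_peak & (trace <= 0.25 * fmax)
    t25 = float(trace_times_min[below][0]) if below.any() else float(trace_times_min[-1])
    in_win = (rate_times_min >= media_switch_min) & (rate_times_min <= t25)
    if not in_win.any():
        raise ValueError("no rate samples inside the analysis window")
    seg = rate_series[in_win]
    seg_t = rate_times_min[in_win]
    k1 = int(np.argmax(seg))
    gp1_rate, gp1_t = float(seg[k1]), float(seg_t[k1])
    later = seg[k1 + 1:]
    later_t = seg_t[k1 + 1:]
    if later.size >= 3:
        peaks, _ = sps.find_peaks(later)
        if peaks.size:
            k2 = peaks[int(np.argmax(later[peaks]))]
            return BiphasicResult(gp1_rate, gp1_t, float(later[k2]), float(later_t[k2]))
    return BiphasicResult(gp1_rate, gp1_t, None, None)


def align_by_first_peak(rate_serieses: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Shift replicate rate curves so their first local maxima coincide."""
    firsts = []
    for s in rate_serieses:
        peaks, _ = sps.find_peaks(s)
        firsts.append(int(peaks[0]) if peaks.size else int(np.argmax(s)))
    ref = min(firsts)
    return [np.asarray(s, float)[f - ref:] for s, f in zip(rate_serieses, firsts)]


def detect_peaks(values: np.ndarray, dt_min: float,
                 min_distance_min: float,
                 min_height: float | None = None) -> OscillationSummary:
    """Local maxima respecting a minimum inter-peak distance and height.

    When two candidates fall closer than the minimum distance the higher one
    is kept (ties resolved toward the earlier peak).
    """
    values = np.asarray(values, dtype=float)
    distance = max(int(np.ceil(min_distance_min / dt_min)), 1)
    peaks, props = sps.find_peaks(values, distance=distance, height=min_height)
    times = peaks * dt_min
    heights = values[peaks]
    return OscillationSummary(peak_times=times, peak_amplitudes=heights,
                              interpeak_cv=phase_drift_cv(times, strict=False))


def oscillation_amplitude(cycle_values: np.ndarray) -> float:
    """Half the min-to-max excursion of one oscillation cycle."""
    cycle_values = np.asarray(cycle_values, dtype=float)
    if cycle_values.size == 0:
        raise ValueError("empty cycle")
    return float(cycle_values.max() - cycle_values.min()) / 2.0


def welch_spectrum(values: np.ndarray, dt_min: float,
                   detrend_points: int = MOVING_MEAN_POINTS,
                   detrended: bool = False) -> SpectrumSummary:
    """Welch power spectrum with a full-length Hamming window (one segment).

    Unless ``detrended`` the trace is first detrended by subtracting its
    20-point moving mean.  Frequencies run up to the Nyquist of the sampling
    grid; power is a density (AU^2 * min).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 * MOVING_MEAN_POINTS:
        raise ValueError("trace too short for a stable spectrum")
    if not detrended:
        values = values - moving_mean(values, detrend_points)
    f, p = sps.welch(values, fs=1.0 / dt_min, window="hamming",
                     nperseg=values.size, noverlap=0, detrend=False,
                     scaling="density")
    return SpectrumSummary(frequencies=f, power=p)


def snr(spectrum: SpectrumSummary) -> float:
    """Band power over supra-band power.

    Signal power is integrated over the configured signal band (set from the
    input period, +/-10 min in period space); noise is the total power at all
    frequencies above the band.  Frequencies below the band are excluded.
    """
    if spectrum.signal_band is None:
        raise ValueError("signal_band must be set (see band_from_period)")
    f_lo, f_hi = spectrum.signal_band
    f, p = spectrum.frequencies, spectrum.power
    in_band = (f >= f_lo) & (f <= f_hi)
    above = f > f_hi
    sig = float(np.sum(p[in_band]))
    noise = float(np.sum(p[above]))
    if noise == 0:
        return float("inf")
    return sig / noise


def bootstrap_snr(spectra: Sequence[SpectrumSummary], B: int = BOOTSTRAP_B,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Bootstrap distribution of the SNR over replicate spectra.

    Replicate spectra are resampled with replacement B times; each iteration
    averages the resampled power spectra and computes one SNR.
    """
    rng = np.random.default_rng(rng)
    if len(spectra) < 1:
        raise ValueError("need at least one replicate spectrum")
    band = spectra[0].signal_band
    if band is None:
        raise ValueError("signal_band must be set on the replicate spectra")
    powers = np.stack([s.power for s in spectra])
    f = spectra[0].frequencies
    out = np.empty(B)
    idx = rng.integers(0, len(spectra), size=(B, len(spectra)))
    for b in range(B):
        mean_p = powers[idx[b]].mean(axis=0)
        out[b] = snr(SpectrumSummary(f, mean_p, band))
    return out


def bootstrap_mean_test(sample_x: np.ndarray, sample_y: np.ndarray,
                        B: int = BOOTSTRAP_B,
                        rng: np.random.Generator | int | None = None,
                        alternative: str = "greater") -> float:
    """Bootstrap test of equal means by pooled resampling.

    The observed statistic is t_obs = mean(x) - mean(y).  The two samples are
    merged; each of B iterations draws n+m observations with replacement,
    takes the mean of the first n minus the mean of the last m as t*, and the
    p-value is the fraction of iterations with t* > t_obs (one-sided
    ``greater``) or |t*| > |t_obs| (``two-sided``).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if B < 1000:
        raise ValueError("B must be at least 1000")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    rng = np.random.default_rng(rng)
    n, m = x.size, y.size
    t_obs = x.mean() - y.mean()
    merged = np.concatenate([x, y])
    draws = rng.integers(0, n + m, size=(B, n + m))
    resampled = merged[draws]
    t_star = resampled[:, :n].mean(axis=1) - resampled[:, n:].mean(axis=1)
    if alternative == "greater":
        count = int(np.sum(t_star > t_obs))
    else:
        count = int(np.sum(np.abs(t_star) > np.abs(t_obs)))
    return count / B


@dataclass
class BootstrapCurves:
    mean_curves: np.ndarray          # (B, n_timepoints)
    mean: np.ndarray
    lower: np.ndarray                # 2.5th percentile
    upper: np.ndarray                # 97.5th percentile
    degenerate: bool = False


def bootstrap_curves(replicate_traces: Sequence[np.ndarray], B: int = BOOTSTRAP_B,
                     rng: np.random.Generator | int | None = None) -> BootstrapCurves:
    """Resample replicate curves with replacement B times and average.

    Returns the full set of B mean curves plus a mean and a 95% percentile
    envelope.  A single replicate yields a degenerate (zero-width) result,
    flagged as such.
    """
    curves = np.stack([np.asarray(t, float) for t in replicate_traces])
    n = curves.shape[0]
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, n, size=(B, n))
    means = curves[idx].mean(axis=1)
    return BootstrapCurves(
        mean_curves=means,
        mean=means.mean(axis=0),
        lower=np.percentile(means, 2.5, axis=0),
        upper=np.percentile(means, 97.5, axis=0),
        degenerate=n < 2,
    )


def max_cross_correlation(trace_a: np.ndarray, trace_b: np.ndarray,
                          dt_min: float, max_lag_min: float) -> tuple[float, float]:
    """(maximum normalized cross-correlation, lag in minutes at the maximum).

    Correlation at lag L is the Pearson correlation between a(t) and b(t+L)
    over their overlap; lags run over [-max_lag, +max_lag]; ties break toward
    the smallest absolute lag (then the negative one).
    """
    a = np.asarray(trace_a, float)
    b = np.asarray(trace_b, float)
    if a.shape != b.shape:
        raise ValueError("traces must share a time grid")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance trace")
    max_shift = int(max_lag_min / dt_min)
    lags = np.arange(-max_shift, max_shift + 1)
    best: tuple[float, int] | None = None
    for lag in sorted(lags, key=lambda l: (abs(l), l)):
        if lag >= 0:
            x, y = a[:a.size - lag] if lag else a, b[lag:]
        else:
            x, y = a[-lag:], b[:b.size + lag]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if best is None or r > best[0]:
            best = (r, lag)
    if best is None:
        raise ValueError("no valid lag (traces too short for max_lag)")
    return best[0], best[1] * dt_min


def phase_drift_cv(peak_times_min: np.ndarray, strict: bool = True) -> float:
    """Coefficient of variation of successive inter-peak intervals.

    Phase drift of an oscillator: SD over mean of the interval distribution.
    Needs at least three peaks; with ``strict=False`` an undefined value is
    returned as nan instead of raising.
    """
    peak_times_min = np.asarray(peak_times_min, float)
    if peak_times_min.size < 3:
        if strict:
            raise ValueError("need at least three peaks to estimate phase drift")
        return float("nan")
    intervals = np.diff(peak_times_min)
    return float(np.std(intervals) / np.mean(intervals))


def modified_zscore(values: np.ndarray) -> np.ndarray:
    """Robust z-score 0.6745 (x - median) / MAD; nan everywhere if MAD is 0."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.full_like(values, np.nan)
    return 0.6745 * (values - med) / mad


def modified_zscore_outliers(chamber_rates: np.ndarray,
                             chamber_ids: Sequence[str] | None = None,
                             threshold: float = OUTLIER_THRESHOLD,
                             min_flagged_timepoints: int = 2) -> dict:
    """Screen chambers whose averaged growth rates are robust outliers.

    ``chamber_rates`` is (n_chambers, n_timepoints).  At each time point the
    modified z-score is computed across chambers; a chamber is excluded when
    |M_i| exceeds the threshold at two or more time points.  Time points with
    zero median absolute deviation are skipped (and reported).
    """
    rates = np.asarray(chamber_rates, dtype=float)
    if rates.ndim != 2:
        raise ValueError("chamber_rates must be 2-D (chambers x time)")
    n_ch, n_t = rates.shape
    if n_ch < 3:
        raise ValueError("need at least three chambers per time point")
    ids = list(chamber_ids) if chamber_ids is not None else [str(i) for i in range(n_ch)]
    flags = np.zeros((n_ch, n_t), dtype=bool)
    skipped = []
    for j in range(n_t):
        z = modified_zscore(rates[:, j])
        if np.all(np.isnan(z)):
            skipped.append(j)
            continue
        flags[:, j] = np.abs(z) > threshold
    counts = flags.sum(axis=1)
    excluded = [ids[i] for i in range(n_ch) if counts[i] >= min_flagged_timepoints]
    return {"excluded": excluded, "flag_counts": dict(zip(ids, counts.tolist())),
            "skipped_timepoints": skipped}


def single_cell_growth_rate(time_min: np.ndarray, area: np.ndarray,
                            window_min: float = SINGLE_CELL_WINDOW_MIN) -> np.ndarray:
    """Windowed relative area growth rate of one tracked cell.

    For each window of ``window_min`` minutes starting at a sample, a line is
    fitted to area vs time and its slope is divided by the mean area in the
    window; the rate (per min) is assigned to the window start.  Tracks
    shorter than one window are rejected.
    """
    time_min = np.asarray(time_min, float)
    area = np.asarray(area, float)
    if time_min.size < 2:
        raise ValueError("track too short")
    dt = float(time_min[1] - time_min[0])
    w = int(round(window_min / dt)) + 1
    if time_min.size < w:
        raise ValueError(f"track shorter than the {window_min}-min window")
    t = np.arange(w) * dt
    t_c = t - t.mean()
    denom = float(np.dot(t_c, t_c))
    win = np.lib.stride_tricks.sliding_window_view(area, w)
    slopes = (win - win.mean(axis=1, keepdims=True)) @ t_c / denom
    return slopes / win.mean(axis=1)


def partner_abundance_correlation(cell_rates: Sequence[np.ndarray],
                                  partner_occupancy: Sequence[np.ndarray],
                                  alpha: float = 0.05,
                                  min_pairs: int = 5) -> list[dict]:
    """Spearman correlation between single-cell growth rates and the fraction
    of the chamber occupied by the partner strain, per time point.

    Each element of ``cell_rates`` / ``partner_occupancy`` holds the paired
    values *across cells at one time point* (not one cell's series); the
    result has one entry per time point with rho, p, and a significance flag
    (p <= alpha).  Time points with too few pairs or constant occupancy are
    flagged invalid.
    """
    out = []
    for rates, occ in zip(cell_rates, partner_occupancy):
        rates = np.asarray(rates, float)
        occ = np.asarray(occ, float)
        entry: dict = {"n": int(rates.size)}
        if rates.size < min_pairs:
            entry.update(rho=float("nan"), p=float("nan"),
                         significant=False, valid=False, reason="too few pairs")
        elif np.all(occ == occ[0]) or np.all(rates == rates[0]):
            entry.update(rho=float("nan"), p=float("nan"),
                         significant=False, valid=False, reason="constant input")
        else:
            rho, p = spstats.spearmanr(occ, rates)
            entry.update(rho=float(rho), p=float(p),
                         significant=bool(p <= alpha), valid=True)
        out.append(entry)
    return out
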
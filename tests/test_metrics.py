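"""Chamber-trace statistics: growth, oscillations, spectra, screening."""

import numpy as np
import pytest

from chamberlink import metrics as mx


# ---------- normalization and smoothing ----------

def test_moving_mean_matches_hand_average():
    v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    sm = mx.moving_mean(v, 3)
    assert sm[2] == pytest.approx(3.0)
    assert sm[0] == pytest.approx(1.5)     # shrunken edge window
    assert mx.moving_mean(v, 1) == pytest.approx(v)


def test_global_normalization_maps_span_to_unit_interval():
    traces = [np.array([2.0, 4.0]), np.array([3.0, 6.0])]
    gmin, gmax = mx.global_normalization_constants(traces)
    norm = mx.normalize_oscillator_trace(np.array([2.0, 6.0]), gmin, gmax,
                                         smooth_points=1)
    assert norm[0] == pytest.approx(0.0)
    assert norm[1] == pytest.approx(1.0)


def test_trace_grid_must_be_uniform_and_increasing():
    with pytest.raises(ValueError):
        mx.ChamberTrace(np.array([0.0, 10.0, 15.0]), np.zeros(3), "c", 25.0, "GFP")
    with pytest.raises(ValueError):
        mx.ChamberTrace(np.array([0.0, 0.0, 10.0]), np.zeros(3), "c", 25.0, "GFP")
    with pytest.raises(ValueError):
        mx.ChamberTrace(np.array([0.0, 10.0]), np.array([1.0, np.nan]),
                        "c", 25.0, "GFP")


# ---------- growth inference ----------

def test_dilution_rate_sign_convention():
    t = np.arange(30) * 10.0
    falling = 1.0 - 0.001 * t
    rates = mx.delta_f_rate(falling, 10.0, 10)
    assert np.allclose(rates, 0.001)        # dilution is positive
    rising = 0.001 * t
    assert np.all(mx.delta_f_rate(rising, 10.0, 10) < 0)
    flat = np.ones(30)
    assert np.allclose(mx.delta_f_rate(flat, 10.0, 10), 0.0)


def test_dilution_rate_requires_full_window():
    with pytest.raises(ValueError):
        mx.delta_f_rate(np.ones(5), 10.0, 10)


def test_doubling_time_inverts_max_rate():
    rates = np.array([0.001, np.log(2.0) / 80.0, 0.002])
    assert mx.doubling_time(rates) == pytest.approx(80.0)
    # doubling all rates halves the doubling time
    assert mx.doubling_time(2 * rates) == pytest.approx(40.0)
    assert np.isinf(mx.doubling_time(np.array([-0.1, 0.0])))


def test_biphasic_peaks_finds_two_separated_growth_phases():
    t = np.arange(0, 1000, 10.0)
    rate = 0.01 * np.exp(-((t - 200) / 50) ** 2) \
        + 0.004 * np.exp(-((t - 600) / 60) ** 2)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * 10.0)))
    trace = np.exp(-cum)
    res = mx.biphasic_peaks(rate, t, trace, t, media_switch_min=50.0)
    assert res.gp1_rate == pytest.approx(0.01, rel=0.01)
    assert res.gp2_rate == pytest.approx(0.004, rel=0.01)
    assert res.gp1_time_min < res.gp2_time_min


def test_single_bump_rate_series_reports_single_phase():
    t = np.arange(0, 500, 10.0)
    rate = 0.01 * np.exp(-((t - 200) / 80) ** 2)
    trace = np.exp(-np.concatenate(([0.0], np.cumsum(
        0.5 * (rate[1:] + rate[:-1]) * 10.0))))
    res = mx.biphasic_peaks(rate, t, trace, t, media_switch_min=0.0)
    assert res.gp2_rate is None or res.gp2_rate < res.gp1_rate


# ---------- oscillation metrics ----------

def test_peak_detection_counts_cycles_of_known_period():
    t = np.arange(0, 1400, 7.0)
    v = np.sin(2 * np.pi * t / 140.0)
    summ = mx.detect_peaks(v, 7.0, min_distance_min=70.0, min_height=0.015)
    assert summ.n_peaks == 10


def test_peak_detection_keeps_taller_of_close_pair():
    t = np.arange(0, 200, 10.0)
    v = np.zeros_like(t)
    v[5] = 1.0     # t = 50
    v[10] = 2.0    # t = 100, 50 min away
    summ = mx.detect_peaks(v, 10.0, min_distance_min=70.0)
    assert summ.n_peaks == 1
    assert summ.peak_times[0] == pytest.approx(100.0)


def test_constant_trace_has_no_peaks():
    summ = mx.detect_peaks(np.ones(50), 10.0, 70.0, 0.015)
    assert summ.n_peaks == 0


def test_amplitude_is_half_peak_to_trough():
    cyc = 3.0 + 2.0 * np.sin(np.linspace(0, 2 * np.pi, 100))
    assert mx.oscillation_amplitude(cyc) == pytest.approx(2.0, rel=1e-3)


def test_phase_drift_cv_zero_for_perfect_clock_and_scale_invariant():
    assert mx.phase_drift_cv(np.arange(5) * 100.0) == pytest.approx(0.0)
    peaks = np.cumsum([0, 100, 100, 140, 60.0])
    iv = np.diff(peaks)
    expect = iv.std() / iv.mean()   # population-SD convention
    assert mx.phase_drift_cv(peaks) == pytest.approx(expect)
    assert mx.phase_drift_cv(peaks * 3.0) == pytest.approx(expect)


def test_cross_correlation_recovers_known_lag():
    t = np.arange(0, 700, 7.0)
    a = np.sin(2 * np.pi * t / 120.0)
    b = np.sin(2 * np.pi * (t - 21.0) / 120.0)
    r, lag = mx.max_cross_correlation(a, b, 7.0, max_lag_min=60.0)
    assert lag == pytest.approx(21.0)
    assert r == pytest.approx(1.0, abs=1e-6)
    # identical traces prefer zero lag over equally good aliases
    r0, lag0 = mx.max_cross_correlation(a, a, 7.0, max_lag_min=240.0)
    assert lag0 == 0.0


# ---------- spectra ----------

def test_spectrum_peaks_at_forcing_frequency():
    t = np.arange(0, 1400, 7.0)
    v = np.sin(2 * np.pi * t / 120.0)
    sp = mx.welch_spectrum(v, 7.0)
    f_peak = sp.frequencies[np.argmax(sp.power)]
    assert f_peak == pytest.approx(1.0 / 120.0, rel=0.15)


def test_signal_band_brackets_input_period():
    sp = mx.SpectrumSummary(np.linspace(0, 0.05, 10), np.ones(10))
    sp.band_from_period(120.0)
    lo, hi = sp.signal_band
    assert lo == pytest.approx(1.0 / 130.0)
    assert hi == pytest.approx(1.0 / 110.0)


def test_snr_separates_in_band_from_out_of_band_content():
    t = np.arange(0, 2100, 7.0)
    rng = np.random.default_rng(0)
    in_band = np.sin(2 * np.pi * t / 120.0) + rng.normal(0, 0.2, t.size)
    sp = mx.welch_spectrum(in_band, 7.0)
    sp.band_from_period(120.0)
    assert mx.snr(sp) > 1.0
    out_band = np.sin(2 * np.pi * t / 40.0) + rng.normal(0, 0.2, t.size)
    sp2 = mx.welch_spectrum(out_band, 7.0)
    sp2.band_from_period(120.0)
    assert mx.snr(sp2) < 1.0


def test_snr_grows_with_in_band_amplitude():
    t = np.arange(0, 2100, 7.0)
    rng = np.random.default_rng(1)
    noise = rng.normal(0, 0.3, t.size)
    snrs = []
    for amp in (0.5, 1.0, 2.0):
        sp = mx.welch_spectrum(amp * np.sin(2 * np.pi * t / 120.0) + noise, 7.0)
        sp.band_from_period(120.0)
        snrs.append(mx.snr(sp))
    assert snrs[0] < snrs[1] < snrs[2]


# ---------- bootstrap ----------

def test_bootstrap_detects_a_large_mean_shift():
    rng = np.random.default_rng(2)
    x = rng.normal(3.0, 1.0, 10)
    y = rng.normal(0.0, 1.0, 10)
    p = mx.bootstrap_mean_test(x, y, B=2000, rng=rng, alternative="greater")
    assert p < 0.01


def test_bootstrap_accepts_identical_samples():
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 1.0, 10)
    p = mx.bootstrap_mean_test(x, x.copy(), B=2000, rng=rng,
                               alternative="greater")
    assert p > 0.2


def test_bootstrap_curve_band_tightens_with_replicates():
    rng = np.random.default_rng(4)
    base = np.sin(np.linspace(0, 6, 80))
    few = [base + rng.normal(0, 0.3, 80) for _ in range(4)]
    many = [base + rng.normal(0, 0.3, 80) for _ in range(32)]
    bc_few = mx.bootstrap_curves(few, B=500, rng=rng)
    bc_many = mx.bootstrap_curves(many, B=500, rng=rng)
    w_few = np.mean(bc_few.upper - bc_few.lower)
    w_many = np.mean(bc_many.upper - bc_many.lower)
    assert w_many < w_few


# ---------- outlier screening ----------

def test_modified_zscore_flags_hand_computed_outlier():
    z = mx.modified_zscore(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
    # median 3, MAD 1: z for 100 is 0.6745 * 97
    assert z[-1] == pytest.approx(0.6745 * 97.0)
    assert np.all(np.abs(z[:-1]) < 3.5)


def test_modified_zscore_degenerate_mad_gives_nan():
    z = mx.modified_zscore(np.array([2.0, 2.0, 2.0, 2.0]))
    assert np.all(np.isnan(z))


def test_single_flagged_timepoint_does_not_exclude():
    rates = np.tile(np.linspace(0.001, 0.002, 8), (5, 1))
    rates += np.arange(5)[:, None] * 1e-6    # break MAD degeneracy
    rates[0, 3] = 1.0                        # one gross excursion
    res = mx.modified_zscore_outliers(rates, list("abcde"))
    assert res["excluded"] == []
    assert res["flag_counts"]["a"] == 1


def test_persistent_deviant_chamber_is_excluded():
    rates = np.tile(np.linspace(0.001, 0.002, 8), (5, 1))
    rates += np.arange(5)[:, None] * 1e-6
    rates[2, 4:] = 1.0                       # deviates at several timepoints
    res = mx.modified_zscore_outliers(rates, list("abcde"))
    assert res["excluded"] == ["c"]


def test_screen_requires_three_chambers():
    with pytest.raises(ValueError):
        mx.modified_zscore_outliers(np.ones((2, 5)))


# ---------- single-cell analysis ----------

def test_single_cell_rate_recovers_exponential_growth():
    t = np.arange(0, 400, 10.0)
    area = 100.0 * np.exp(0.004 * t)
    rates = mx.single_cell_growth_rate(t, area, window_min=100.0)
    assert np.allclose(rates, 0.004, rtol=0.02)
    assert np.allclose(mx.single_cell_growth_rate(t, np.full(t.size, 50.0)), 0.0)
    assert np.all(mx.single_cell_growth_rate(t, 100.0 * np.exp(-0.004 * t)) < 0)


def test_short_tracks_are_rejected():
    t = np.arange(0, 60, 10.0)
    with pytest.raises(ValueError):
        mx.single_cell_growth_rate(t, np.exp(0.01 * t), window_min=100.0)


def test_partner_correlation_perfect_monotone_and_invariance():
    rates = [np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])]
    occ = [np.array([0.1, 0.2, 0.3, 0.5, 0.7, 0.9])]
    res = mx.partner_abundance_correlation(rates, occ)
    assert res[0]["rho"] == pytest.approx(1.0)
    # monotone transform of either variable leaves rho unchanged
    res2 = mx.partner_abundance_correlation([np.exp(rates[0])], [occ[0] ** 3])
    assert res2[0]["rho"] == pytest.approx(1.0)


def test_partner_correlation_flags_degenerate_inputs():
    res = mx.partner_abundance_correlation(
        [np.array([1.0, 2.0, 3.0, 4.0, 5.0])],
        [np.full(5, 0.4)])
    assert not res[0]["valid"]
    res2 = mx.partner_abundance_correlation([np.array([1.0, 2.0])],
                                            [np.array([0.1, 0.2])])
    assert res2[0]["reason"] == "too few pairs"
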
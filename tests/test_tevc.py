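"""Voltage-clamp analysis: reversal, Q10 fitting, threshold, lag."""

import numpy as np
import pytest

from thermokit import synthetic, tevc


FS = 10.0
RATE = 2.5 / 60.0  # C per s


def ramp_trace(q10=4.0, t0=25.0, i0=2.0, t_min=10.0, t_max=35.0):
    """Noiseless single-regime exponential current over a linear ramp."""
    t = np.arange(0.0, (t_max - t_min) / RATE, 1.0 / FS)
    temp = t_min + RATE * t
    current = -(i0 * q10 ** ((temp - t0) / 10.0))
    return tevc.TEVCTrace(t, current, np.full(t.size, -60.0), temp, FS)


def gen_ramp(noise=0.0, seed=0, params=None):
    protocol = (
        synthetic.TemperatureProtocol(bath_tau_s=2.0)
        .hold(60.0, 10.0)
        .ramp(10.0, 35.0, RATE)
    )
    return synthetic.gen_tevc(
        protocol, -60.0, params or synthetic.ChannelParams(),
        noise_sd_nA=noise, seed=seed,
    )


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

def test_trace_validation():
    t = np.arange(5.0)
    with pytest.raises(tevc.AnalysisError):
        tevc.TEVCTrace(t, np.zeros(4), np.zeros(5), np.zeros(5), 1.0)
    with pytest.raises(tevc.AnalysisError):
        tevc.TEVCTrace(t[::-1], np.zeros(5), np.zeros(5), np.zeros(5), 1.0)


def test_trace_window():
    tr = ramp_trace()
    sub = tr.window(10.0, 20.0)
    assert sub.time_s[0] >= 10.0 and sub.time_s[-1] <= 20.0
    assert len(sub) < len(tr)


# ---------------------------------------------------------------------------
# reversal potentials
# ---------------------------------------------------------------------------

def test_estimate_reversal_exact_interpolation():
    v = np.arange(-60.0, 41.0, 20.0)
    i = 0.5 * (v + 12.0)  # crosses zero at exactly -12 mV
    est = tevc.estimate_reversal(tevc.IVCurve(v, i, 22.0))
    assert est.erev_mV == pytest.approx(-12.0, abs=1e-9)
    assert not est.ambiguous


def test_estimate_reversal_no_crossing_raises():
    v = np.arange(-60.0, 41.0, 20.0)
    with pytest.raises(tevc.AnalysisError, match="no reversal"):
        tevc.estimate_reversal(tevc.IVCurve(v, np.abs(v) + 1.0, 22.0))


def test_estimate_reversal_multiple_crossings_flagged():
    v = np.array([-60.0, -40.0, -20.0, 0.0, 20.0])
    i = np.array([-1.0, 1.0, -1.0, 1.0, 2.0])  # three crossings
    est = tevc.estimate_reversal(tevc.IVCurve(v, i, 22.0))
    assert est.ambiguous
    # closest crossing to the median command voltage (-20 mV)
    assert -30.0 <= est.erev_mV <= -10.0


def test_iv_from_steps_steady_state_mean():
    fs = 100.0
    t = np.arange(0.0, 4.0, 1.0 / fs)
    v = np.where(t < 2.0, -40.0, 20.0)
    i = np.where(t < 2.0, -3.0, 5.0)
    tr = tevc.TEVCTrace(t, i, v, np.full(t.size, 22.0), fs)
    iv = tevc.iv_from_steps(tr, [(0.0, 2.0), (2.0, 4.0)])
    assert iv.voltages_mV.tolist() == [-40.0, 20.0]
    assert iv.currents_nA == pytest.approx([-3.0, 5.0])


# ---------------------------------------------------------------------------
# Q10 fitting
# ---------------------------------------------------------------------------

def test_fit_q10_single_regime_exact():
    fit = tevc.fit_q10(ramp_trace(q10=4.0), threshold_C=10.0, baseline=0.0)
    assert fit.q10_low == pytest.approx(4.0, abs=1e-6)
    assert fit.q10_high == pytest.approx(4.0, abs=1e-6)
    assert fit.single_regime


def test_fit_q10_invariants():
    fit = tevc.fit_q10(gen_ramp())
    assert fit.q10_low == pytest.approx(10.0 ** (10.0 * fit.slope_low))
    assert fit.q10_high == pytest.approx(10.0 ** (10.0 * fit.slope_high))
    (lo0, lo1), (hi0, hi1) = fit.fit_ranges
    assert lo0 < lo1 <= hi0 < hi1  # disjoint and ordered
    assert fit.q10_low > 0 and fit.q10_high > 0


def test_fit_q10_noiseless_generator_recovery():
    params = synthetic.ChannelParams()
    fit = tevc.fit_q10(gen_ramp(), threshold_C=params.threshold_C)
    assert fit.q10_low == pytest.approx(params.q10_low, rel=0.01)
    assert fit.q10_high == pytest.approx(params.q10_high, rel=0.01)
    assert fit.breakpoint_C == pytest.approx(params.breakpoint_C, abs=0.25)
    assert not fit.single_regime


def test_fit_q10_scale_invariance():
    tr = gen_ramp()
    scaled = tevc.TEVCTrace(
        tr.time_s, 3.7 * tr.current_nA, tr.voltage_mV, tr.temperature_C, FS
    )
    f1, f2 = tevc.fit_q10(tr), tevc.fit_q10(scaled)
    assert f1.q10_low == pytest.approx(f2.q10_low, rel=1e-9)
    assert f1.breakpoint_C == f2.breakpoint_C


def test_fit_q10_mean_recovery_under_5pct_noise():
    # Q10 = 10^(10 s) is convex in the fitted slope, so per-seed slope noise
    # inflates an arithmetic mean of Q10s; averaging the slopes (geometric
    # mean of the Q10s) is the aggregation that tests estimator bias.
    params = synthetic.ChannelParams()
    peak = float(np.abs(gen_ramp().current_nA).max())
    slopes_low, slopes_high = [], []
    for seed in range(20):
        fit = tevc.fit_q10(gen_ramp(noise=0.05 * peak, seed=300 + seed))
        slopes_low.append(fit.slope_low)
        slopes_high.append(fit.slope_high)
    mean_q10_low = 10.0 ** (10.0 * np.mean(slopes_low))
    mean_q10_high = 10.0 ** (10.0 * np.mean(slopes_high))
    assert mean_q10_low == pytest.approx(params.q10_low, rel=0.10)
    assert mean_q10_high == pytest.approx(params.q10_high, rel=0.10)


def test_fit_q10_rejects_nonmonotone_and_short():
    tr = ramp_trace()
    temp = tr.temperature_C.copy()
    temp[temp.size // 2] = temp.max()  # break monotonicity
    broken = tevc.TEVCTrace(tr.time_s, tr.current_nA, tr.voltage_mV, temp, FS)
    with pytest.raises(tevc.AnalysisError, match="monotone"):
        tevc.fit_q10(broken)
    short = tr.window(0.0, 60.0)  # only a few degrees of ramp
    with pytest.raises(tevc.AnalysisError):
        tevc.fit_q10(short)


# ---------------------------------------------------------------------------
# threshold detection
# ---------------------------------------------------------------------------

def test_detect_threshold_on_generator():
    peak = float(np.abs(gen_ramp().current_nA).max())
    tr = gen_ramp(noise=0.005 * peak, seed=11)
    assert tevc.detect_threshold(tr) == pytest.approx(14.0, abs=0.5)


def test_detect_threshold_step_onset_exact():
    t = np.arange(0.0, 600.0, 1.0 / FS)
    temp = 10.0 + RATE * t
    current = np.where(temp >= 20.0, -5.0, 0.0)
    tr = tevc.TEVCTrace(t, current, np.full(t.size, -60.0), temp, FS)
    assert tevc.detect_threshold(tr) == pytest.approx(20.0, abs=0.1)


def test_detect_threshold_flat_noise_raises():
    rng = np.random.default_rng(0)
    t = np.arange(0.0, 600.0, 1.0 / FS)
    temp = 10.0 + RATE * t
    tr = tevc.TEVCTrace(
        t, rng.normal(0.0, 1.0, t.size), np.full(t.size, -60.0), temp, FS
    )
    with pytest.raises(tevc.AnalysisError):
        tevc.detect_threshold(tr)


# ---------------------------------------------------------------------------
# cross-correlation lag
# ---------------------------------------------------------------------------

def test_xcorr_lag_recovers_constructed_shift():
    t = np.arange(0.0, 360.0, 1.0 / FS)
    temp = 20.0 + 8.0 * (np.sin(2 * np.pi * t / 120.0) > 0)
    shift_s = 2.3
    current = -np.interp(t - shift_s, t, temp - 20.0)
    tr = tevc.TEVCTrace(t, current, np.full(t.size, -60.0), temp, FS)
    lag = tevc.xcorr_lag(tr, max_lag_s=20.0)
    assert lag.lag_s == pytest.approx(shift_s, abs=0.2)
    assert lag.peak_correlation > 0.9


def test_xcorr_lag_slow_channel_exceeds_fast():
    protocol = synthetic.TemperatureProtocol(bath_tau_s=0.5)
    for _ in range(3):
        protocol.hold(60.0, 20.0).hold(60.0, 28.0)
    slow = synthetic.gen_tevc(
        protocol, -60.0, synthetic.ChannelParams(channel_tau_s=5.0), seed=3
    )
    fast = synthetic.gen_tevc(
        protocol, -60.0, synthetic.ChannelParams(channel_tau_s=0.5), seed=3
    )
    lag_slow = tevc.xcorr_lag(slow, max_lag_s=20.0).lag_s
    lag_fast = tevc.xcorr_lag(fast, max_lag_s=20.0).lag_s
    assert lag_slow > lag_fast > 0.0
    assert 2.0 <= lag_slow <= 8.0


def test_xcorr_lag_constant_channel_raises():
    t = np.arange(0.0, 100.0, 1.0 / FS)
    tr = tevc.TEVCTrace(
        t, np.zeros(t.size), np.full(t.size, -60.0), np.full(t.size, 20.0), FS
    )
    with pytest.raises(tevc.AnalysisError):
        tevc.xcorr_lag(tr, max_lag_s=5.0)


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------

def test_temperature_sensitivity_model_summary():
    results = tevc.TemperatureSensitivityModel(gen_ramp()).fit()
    params = results.params
    assert params["q10_low"] == pytest.approx(9.05, rel=0.01)
    text = results.summary()
    assert "Q10" in text and "breakpoint" in text.lower()
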
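"""Heat-box behavior: incapacitation calling, Kaplan-Meier, log-rank."""

import numpy as np
import pandas as pd
import pytest

from thermokit import behavior


E0, E1 = 120.0, 480.0  # exposure window used by the constructed traces


def constructed_trace(freeze_at=None, resume_at=None, total_s=1800.0, walk_mask=None):
    """1 Hz walk at +/-0.5 cm steps; optionally frozen on [freeze_at, resume_at)."""
    t = np.arange(0.0, total_s + 1.0)
    pos = np.where(t.astype(int) % 2 == 0, 1.0, 2.0)
    temp = np.where((t >= E0) & (t < E1), 36.0, 22.0)
    moving = np.ones(t.size, dtype=bool)
    if freeze_at is not None:
        stop = resume_at if resume_at is not None else total_s + 1.0
        moving &= ~((t >= freeze_at) & (t < stop))
    if walk_mask is not None:
        moving &= walk_mask(t)
    pos = np.where(moving, pos, np.nan)
    # frozen samples hold the last moving position
    last = 1.0
    for i in range(pos.size):
        if np.isnan(pos[i]):
            pos[i] = last
        else:
            last = pos[i]
    return behavior.PositionTrace(t, pos, temp)


# ---------------------------------------------------------------------------
# container and exposure inference
# ---------------------------------------------------------------------------

def test_position_trace_validation():
    t = np.arange(10.0)
    with pytest.raises(behavior.AnalysisError):
        behavior.PositionTrace(t, np.ones(9), np.full(10, 22.0))
    with pytest.raises(behavior.AnalysisError):
        behavior.PositionTrace(t[::-1], np.ones(10), np.full(10, 22.0))
    with pytest.raises(behavior.AnalysisError, match="chamber"):
        behavior.PositionTrace(t, np.full(10, 5.0), np.full(10, 22.0))


def test_infer_exposure_finds_hot_plateau():
    tr = constructed_trace()
    e0, e1 = behavior.infer_exposure(tr)
    assert e0 == pytest.approx(E0)
    assert e1 == pytest.approx(E1)  # exclusive end: first cold sample


# ---------------------------------------------------------------------------
# incapacitation calling: exact constructed cases
# ---------------------------------------------------------------------------

def test_incapacitation_time_exact():
    # freeze 10 s into the exposure: the position at second e0+10 already
    # equals the held value, so that is the first inactive second
    tr = constructed_trace(freeze_at=E0 + 10.0)
    rec = behavior.detect_incapacitation(tr, exposure_s=(E0, E1))
    assert rec.incapacitated
    assert not rec.incapacitation_censored
    assert rec.time_to_incapacitation_s == pytest.approx(10.0)
    assert rec.exposure_temperature_C == pytest.approx(36.0)


def test_never_incapacitated_is_censored_at_exposure_duration():
    rec = behavior.detect_incapacitation(constructed_trace(), exposure_s=(E0, E1))
    assert not rec.incapacitated
    assert rec.incapacitation_censored
    assert rec.time_to_incapacitation_s == pytest.approx(E1 - E0)
    assert rec.time_to_recovery_s is None


def test_just_below_criterion_is_not_called():
    # 44 s frozen then walking again: no 90 s window holds 45 inactive seconds
    tr = constructed_trace(freeze_at=E0 + 10.0, resume_at=E0 + 54.0)
    rec = behavior.detect_incapacitation(tr, exposure_s=(E0, E1))
    assert not rec.incapacitated
    # 46 s frozen qualifies (45 inactive seconds strictly after the freeze)
    tr2 = constructed_trace(freeze_at=E0 + 10.0, resume_at=E0 + 56.0)
    assert behavior.detect_incapacitation(tr2, exposure_s=(E0, E1)).incapacitated


def test_cumulative_vs_contiguous_modes():
    # repeating 30 s frozen / 10 s walking: cumulative reaches 45-in-90 but
    # no contiguous run is 45 s long
    def mask(t):
        return (t < E0) | (t >= E1) | (((t - E0) % 40.0) >= 30.0)

    tr = constructed_trace(walk_mask=mask)
    cum = behavior.detect_incapacitation(tr, exposure_s=(E0, E1), mode="cumulative")
    con = behavior.detect_incapacitation(tr, exposure_s=(E0, E1), mode="contiguous")
    assert cum.incapacitated
    assert not con.incapacitated
    with pytest.raises(behavior.AnalysisError):
        behavior.detect_incapacitation(tr, exposure_s=(E0, E1), mode="bogus")


def test_recovery_time_from_exposure_end():
    # frozen from exposure+10 until 600 s absolute, then walks again
    tr = constructed_trace(freeze_at=E0 + 10.0, resume_at=600.0)
    rec = behavior.detect_incapacitation(tr, exposure_s=(E0, E1))
    assert rec.incapacitated and rec.recovered
    assert not rec.recovery_censored
    # walking resumes at second 600; measured from exposure end (480)
    assert rec.time_to_recovery_s == pytest.approx(600.0 - E1)


def test_recovery_censored_at_horizon():
    tr = constructed_trace(freeze_at=E0 + 10.0, total_s=E1 + 2000.0)
    rec = behavior.detect_incapacitation(tr, exposure_s=(E0, E1))
    assert rec.incapacitated and not rec.recovered
    assert rec.recovery_censored
    assert rec.time_to_recovery_s == pytest.approx(behavior.RECOVERY_HORIZON_S)


def test_recovery_censored_by_trace_end():
    tr = constructed_trace(freeze_at=E0 + 10.0, total_s=E1 + 300.0)
    rec = behavior.detect_incapacitation(tr, exposure_s=(E0, E1))
    assert rec.recovery_censored
    assert rec.time_to_recovery_s == pytest.approx(300.0)


def test_time_shift_invariance():
    tr = constructed_trace(freeze_at=E0 + 10.0, resume_at=600.0)
    shifted = behavior.PositionTrace(
        tr.time_s + 100.0, tr.position_cm, tr.temperature_C
    )
    a = behavior.detect_incapacitation(tr, exposure_s=(E0, E1))
    b = behavior.detect_incapacitation(shifted, exposure_s=(E0 + 100.0, E1 + 100.0))
    assert b.time_to_incapacitation_s == pytest.approx(a.time_to_incapacitation_s)
    assert b.time_to_recovery_s == pytest.approx(a.time_to_recovery_s)


def test_detect_rejects_short_exposure_and_uncovered_trace():
    tr = constructed_trace()
    with pytest.raises(behavior.AnalysisError, match="window"):
        behavior.detect_incapacitation(tr, exposure_s=(E0, E0 + 60.0))
    with pytest.raises(behavior.AnalysisError, match="cover"):
        behavior.detect_incapacitation(tr, exposure_s=(E0, tr.time_s[-1] + 100.0))
    with pytest.raises(behavior.AnalysisError):
        behavior.detect_incapacitation(tr, exposure_s=(E0, E1), motion_eps_cm=0.0)


def test_events_to_frame_columns():
    recs = [behavior.detect_incapacitation(constructed_trace(), exposure_s=(E0, E1))]
    frame = behavior.events_to_frame(recs)
    assert len(frame) == 1
    for col in (
        "fly_id", "genotype", "incapacitated",
        "time_to_incapacitation_s", "recovery_censored",
    ):
        assert col in frame.columns


# ---------------------------------------------------------------------------
# Kaplan-Meier against a brute-force product-limit oracle
# ---------------------------------------------------------------------------

def km_oracle(times, events):
    """Textbook product-limit estimate over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out_t, out_s, out_v = [0.0], [1.0], [0.0]
    s, greenwood = 1.0, 0.0
    for t in np.unique(times[events]):
        n = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / n
        if n - d > 0:
            greenwood += d / (n * (n - d))
        out_t.append(float(t))
        out_s.append(s)
        out_v.append(s ** 2 * greenwood)
    return np.array(out_t), np.array(out_s), np.array(out_v)


def test_km_matches_oracle_with_ties_and_censoring():
    rng = np.random.default_rng(42)
    times = rng.integers(1, 8, size=20).astype(float)  # many ties
    events = rng.random(20) < 0.7
    curve = behavior.km_estimate(times, events)
    t_o, s_o, v_o = km_oracle(times, events)
    for t, s, v in zip(t_o, s_o, v_o):
        assert curve.probability_at(t) == pytest.approx(s, abs=1e-12)
        idx = np.searchsorted(curve.times_s, t, side="right") - 1
        assert curve.variance[idx] == pytest.approx(v, abs=1e-12)


def test_km_step_function_and_bounds():
    curve = behavior.km_estimate([2.0, 4.0, 6.0], [True, True, False])
    assert curve.times_s[0] == 0.0 and curve.survival[0] == 1.0
    assert curve.probability_at(1.9) == 1.0
    assert curve.probability_at(2.0) == pytest.approx(2.0 / 3.0)
    assert curve.probability_at(100.0) == pytest.approx(1.0 / 3.0)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    with pytest.raises(behavior.AnalysisError):
        behavior.km_estimate([], [])
    with pytest.raises(behavior.AnalysisError):
        behavior.km_estimate([-1.0], [True])


def test_median_survival():
    curve = behavior.km_estimate([1.0, 2.0, 3.0, 4.0], [True] * 4)
    assert behavior.median_survival(curve) == pytest.approx(2.0)
    flat = behavior.km_estimate([5.0, 6.0, 7.0, 8.0], [True, False, False, False])
    assert np.isnan(behavior.median_survival(flat))


# ---------------------------------------------------------------------------
# log-rank against a hand-computed oracle
# ---------------------------------------------------------------------------

def logrank_oracle(ta, ea, tb, eb):
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for t in all_t:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & ea)
        db = np.sum((tb == t) & eb)
        n, d = na + nb, da + db
        if n < 2:
            continue
        e_a = d * na / n
        o_minus_e += da - e_a
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def test_logrank_matches_oracle():
    rng = np.random.default_rng(9)
    ta = rng.integers(1, 10, 15).astype(float)
    tb = (rng.integers(1, 10, 12) + 2).astype(float)
    ea = rng.random(15) < 0.8
    eb = rng.random(12) < 0.8
    res = behavior.logrank_test(ta, ea, tb, eb)
    assert res.chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-9)
    assert 0.0 <= res.p_value <= 1.0
    assert "chi2" in res.summary()


def test_logrank_identical_groups_is_null():
    t = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
    e = np.array([True, True, False, True, True])
    res = behavior.logrank_test(t, e, t, e)
    assert res.chi2 == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(behavior.AnalysisError):
        behavior.logrank_test([], [], t, e)
    with pytest.raises(behavior.AnalysisError):
        behavior.logrank_test(t, np.zeros(5, bool), t, np.zeros(5, bool))


# ---------------------------------------------------------------------------
# temperature-response table
# ---------------------------------------------------------------------------

def test_incapacitation_by_temperature():
    rows = []
    first_incap = {"f1": 34.0, "f2": 38.0, "f3": 34.0, "f4": None}
    for fly, first in first_incap.items():
        for temp in (30.0, 34.0, 38.0):
            rows.append(
                {
                    "fly_id": fly,
                    "exposure_temperature_C": temp,
                    "incapacitated": first is not None and temp >= first,
                }
            )
    series = behavior.incapacitation_by_temperature(pd.DataFrame(rows))
    assert series[30.0] == pytest.approx(1.0)
    assert series[34.0] == pytest.approx(0.5)
    assert series[38.0] == pytest.approx(0.25)
    assert np.all(np.diff(series.to_numpy()) <= 1e-12)
    with pytest.raises(behavior.AnalysisError, match="columns"):
        behavior.incapacitation_by_temperature(pd.DataFrame({"fly_id": ["f1"]}))
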
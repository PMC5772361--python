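"""One-shot reproduction of the package's headline quantities.

Every number here is recomputed at run time by the library's own pipelines:
the closed-form electrochemistry runs on the published solution recipes and
measured reversal potentials; everything that would need raw recordings runs
instead on the synthetic generators configured with the study conditions,
and the pipelines' ability to recover the generating parameters is the
reported quantity.

:func:`run_report` returns both the machine-readable quantities (value +
problem size) and a pass/fail check table used by the ``reproduce`` CLI
subcommand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import behavior, biophysics, calcium, synthetic, tevc

__all__ = ["Quantity", "Check", "run_report", "quantities_json"]


@dataclass
class Quantity:
    name: str
    value: float
    n: int
    note: str = ""


@dataclass
class Check:
    name: str
    passed: bool
    detail: str


def _seeds(seed: int, n: int) -> list[int]:
    # independent child seeds below 2**31
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# closed-form electrochemistry on the published numbers
# ---------------------------------------------------------------------------

def nernst_quantities() -> list[Quantity]:
    t = 35.0
    q = [
        Quantity("nernst_na_96_7_mV",
                 biophysics.nernst_potential(biophysics.NA, 96.0, 7.0, t), 1),
        Quantity("nernst_k_2_100_mV",
                 biophysics.nernst_potential(biophysics.K, 2.0, 100.0, t), 1),
        Quantity("nernst_na_48_7_mV",
                 biophysics.nernst_potential(biophysics.NA, 48.0, 7.0, t), 1),
        Quantity("nernst_na_2_7_mV",
                 biophysics.nernst_potential(biophysics.NA, 2.0, 7.0, t), 1),
    ]
    return q


#: measured reversal potentials (mV) of the sodium-substitution series
MEASURED_EREVS = {96.0: -12.0, 48.0: -23.7, 2.0: -59.0}

#: the reported equilibrium potentials (mV, rounded to the precision they
#: were reported at); these are the inputs the shift arithmetic operates on
REPORTED_E_NA = {96.0: 69.0, 48.0: 51.0, 2.0: -33.0}
REPORTED_E_K = -104.0


def selectivity_quantities() -> list[Quantity]:
    """Shift-ratio selectivity arithmetic on the reported potentials.

    The measured reversal potentials and the mV-rounded equilibrium
    potentials of the substitution series are the inputs; the chord-model
    arithmetic (shift ratios, two-ion brackets, remainder bound) is the
    computation.  The calcium equilibrium potential is computed from the
    solution compositions (1.8 / 0.1 mM at 35 C) since its reported value
    is inconsistent with the recipe.
    """
    erev_ref = MEASURED_EREVS[96.0]
    f_48 = biophysics.fraction_from_shift(
        erev_ref, MEASURED_EREVS[48.0], REPORTED_E_NA[96.0], REPORTED_E_NA[48.0]
    )
    f_2 = biophysics.fraction_from_shift(
        erev_ref, MEASURED_EREVS[2.0], REPORTED_E_NA[96.0], REPORTED_E_NA[2.0]
    )
    f_na = 0.5 * (f_48 + f_2)
    e_ca = biophysics.nernst_potential(biophysics.CA, 1.8, 0.1, 35.0)
    k_hi = biophysics.two_ion_chord_fraction(erev_ref, REPORTED_E_K, REPORTED_E_NA[96.0])
    k_lo = biophysics.two_ion_chord_fraction(erev_ref, REPORTED_E_K, e_ca)
    ca_hi = biophysics.remainder_bound({"Na": f_na, "K": k_lo})
    return [
        Quantity("relative_na_conductance_96_48_pct", f_48 * 100.0, 1),
        Quantity("relative_na_conductance_96_2_pct", f_2 * 100.0, 1),
        Quantity("relative_na_conductance_mean_pct", f_na * 100.0, 2),
        Quantity("relative_k_conductance_upper_pct", k_hi * 100.0, 1),
        Quantity("relative_k_conductance_lower_pct", k_lo * 100.0, 1),
        Quantity("relative_ca_conductance_bound_pct", ca_hi * 100.0, 1),
    ]


# ---------------------------------------------------------------------------
# voltage-clamp pipeline on the generators
# ---------------------------------------------------------------------------

def _ramp_protocol() -> synthetic.TemperatureProtocol:
    # slow 2.5 C per 60 s ramp from 10 to 35 C, the ramp analyzed by the fits
    return (
        synthetic.TemperatureProtocol(bath_tau_s=2.0)
        .hold(60.0, 10.0)
        .ramp(10.0, 35.0, 2.5 / 60.0)
    )


def tevc_quantities(seed: int) -> list[Quantity]:
    params = synthetic.ChannelParams()  # Q10 9.05 / 5.20, threshold 14, breakpoint 20
    quantities: list[Quantity] = []

    # noiseless ramp -> two-regime Q10 fit
    ramp = synthetic.gen_tevc(_ramp_protocol(), -60.0, params, sample_rate_hz=10.0, seed=seed)
    fit = tevc.fit_q10(ramp, threshold_C=params.threshold_C)
    n = len(ramp)
    quantities += [
        Quantity("q10_below_breakpoint", fit.q10_low, n),
        Quantity("q10_above_breakpoint", fit.q10_high, n),
        Quantity("q10_breakpoint_C", fit.breakpoint_C, n),
    ]

    # threshold detection on a lightly noisy ramp
    peak = float(np.abs(ramp.current_nA).max())
    noisy = synthetic.gen_tevc(
        _ramp_protocol(), -60.0, params, noise_sd_nA=0.005 * peak,
        sample_rate_hz=10.0, seed=seed + 1,
    )
    quantities.append(
        Quantity("activation_threshold_C", tevc.detect_threshold(noisy), len(noisy))
    )

    # Q10 recovery under noise: error of the mean recovered Q10s across seeds
    lows, highs = [], []
    for s in _seeds(seed + 2, 20):
        tr = synthetic.gen_tevc(
            _ramp_protocol(), -60.0, params, noise_sd_nA=0.02 * peak,
            sample_rate_hz=10.0, seed=s,
        )
        f = tevc.fit_q10(tr, threshold_C=params.threshold_C)
        lows.append(f.q10_low)
        highs.append(f.q10_high)
    err = max(
        abs(float(np.mean(lows)) - params.q10_low) / params.q10_low,
        abs(float(np.mean(highs)) - params.q10_high) / params.q10_high,
    )
    quantities.append(Quantity("q10_noisy_recovery_error_pct", 100.0 * err, 20))

    # current lags temperature across steps (slow channel kinetics hypothesis)
    step_params = synthetic.ChannelParams(channel_tau_s=5.0)
    protocol = synthetic.TemperatureProtocol(bath_tau_s=0.5)
    for _ in range(3):
        protocol.hold(60.0, 20.0).hold(60.0, 28.0)
    steps = synthetic.gen_tevc(protocol, -60.0, step_params, sample_rate_hz=10.0, seed=seed + 3)
    lag = tevc.xcorr_lag(steps, max_lag_s=20.0)
    quantities.append(Quantity("current_temperature_lag_s", lag.lag_s, len(steps)))
    fast = synthetic.gen_tevc(
        protocol, -60.0, synthetic.ChannelParams(channel_tau_s=0.5),
        sample_rate_hz=10.0, seed=seed + 3,
    )
    quantities.append(
        Quantity(
            "current_temperature_lag_fast_channel_s",
            tevc.xcorr_lag(fast, max_lag_s=20.0).lag_s,
            len(fast),
        )
    )

    # non-inactivation over a 100 s plateau at 28 C
    plateau_protocol = synthetic.TemperatureProtocol(bath_tau_s=0.5).hold(20.0, 10.0).hold(100.0, 28.0)
    plateau = synthetic.gen_tevc(plateau_protocol, -60.0, params, sample_rate_hz=10.0, seed=seed + 4)
    t0 = 20.0 + 10.0  # skip the bath settling transient
    first = np.abs(plateau.current_nA[(plateau.time_s >= t0) & (plateau.time_s < t0 + 10.0)]).mean()
    last = np.abs(plateau.current_nA[plateau.time_s >= 110.0]).mean()
    quantities.append(Quantity("plateau_current_ratio_last_over_first", float(last / first), len(plateau)))

    # full selectivity round trip: simulate the substitution series, estimate
    # reversals, run the shift-ratio inference, compare to the generating fraction
    erevs = {}
    for c_na in (96.0, 48.0, 2.0):
        conc = {"Na": c_na, "K": 2.0, "Ca": 1.8}
        if c_na < 96.0:
            conc["NMDG"] = 96.0 - c_na  # impermeant substitute, no Nernst term
        sol = biophysics.SolutionComposition(f"ND96-Na{c_na:g}", conc)
        iv = synthetic.simulate_iv(params, outside=sol, temperature_C=35.0)
        erevs[c_na] = tevc.estimate_reversal(iv).erev_mV
    sel = biophysics.SelectivityModel.from_nd96_series(erevs).fit()
    recovered = sel.point_fractions["Na"]
    quantities += [
        Quantity("sim_recovered_na_fraction_pct", recovered * 100.0, 3),
        Quantity("sim_na_fraction_recovery_error",
                 abs(recovered - params.fractions["Na"]), 3),
    ]
    return quantities


# ---------------------------------------------------------------------------
# calcium pipeline
# ---------------------------------------------------------------------------

#: published group summaries of the epoch dF/F statistic
DFF_CONTROL = (-0.1524, 0.1358, 21)
DFF_CHANNEL = (0.03656, 0.10, 20)


def calcium_quantities(seed: int) -> list[Quantity]:
    quantities: list[Quantity] = []

    # power of the Welch t-test at the published group parameters
    rng = np.random.default_rng(seed)
    n_draws = 1000
    hits = 0
    (mu_a, sd_a, n_a), (mu_b, sd_b, n_b) = DFF_CONTROL, DFF_CHANNEL
    for _ in range(n_draws):
        a = rng.normal(mu_a, sd_a, n_a)
        b = rng.normal(mu_b, sd_b, n_b)
        _, p = stats.ttest_ind(a, b, equal_var=False)
        if p < 1e-5:
            hits += 1
    quantities.append(Quantity("dff_ttest_power_pct", 100.0 * hits / n_draws, n_draws))

    # spectrogram ridge on a known tone
    fs, f_tone, dur = 40.0, 1.5, 120.0
    t = np.arange(0.0, dur, 1.0 / fs)
    tone = 100.0 + 10.0 * np.sin(2 * np.pi * f_tone * t)
    trace = calcium.FluorescenceTrace(t, tone, np.full(t.size, 19.0), 1.0 / fs)
    spec = calcium.morlet_cwt(trace)
    interior = ~spec.coi
    power = np.where(interior, spec.magnitude, 0.0).sum(axis=1)
    ridge = float(spec.frequencies_hz[int(np.argmax(power))])
    quantities.append(Quantity("cwt_ridge_error_hz", abs(ridge - f_tone), t.size))

    # sign consistency of dF/F on the generators
    protocol = (
        synthetic.TemperatureProtocol(bath_tau_s=2.0)
        .hold(240.0, 19.0).hold(240.0, 28.0).hold(240.0, 19.0).hold(240.0, 28.0)
    )
    pos = 0
    seeds = _seeds(seed + 1, 20)
    for s in seeds:
        tr = synthetic.gen_calcium(synthetic.SpikingParams(), protocol, seed=s)
        epochs = calcium.epoch_segments(tr.time_s, tr.temperature_C, 19.0, 28.0)
        if calcium.delta_f_over_f(tr, epochs).delta_f_over_f > 0:
            pos += 1
    quantities.append(Quantity("dff_sign_consistency_pct", 100.0 * pos / len(seeds), len(seeds)))
    return quantities


# ---------------------------------------------------------------------------
# behavior pipeline
# ---------------------------------------------------------------------------

def _run_cohort(temp_C: float, n_flies: int, seed: int, params=None):
    params = params or synthetic.FlyWalkParams()
    protocol = synthetic.HeatBoxProtocol(test_temp_C=temp_C)
    traces = synthetic.gen_fly_walks(params, n_flies, protocol, seed=seed)
    records = [
        behavior.detect_incapacitation(tr, exposure_s=protocol.exposure_interval_s)
        for tr in traces
    ]
    return records


def behavior_quantities(seed: int, n_flies: int = 300) -> list[Quantity]:
    quantities: list[Quantity] = []
    medians = {}
    seeds = _seeds(seed, 6)
    for i, temp in enumerate((34.0, 36.0, 38.0, 40.0)):
        records = _run_cohort(temp, n_flies, seeds[i])
        incap = [r for r in records if r.incapacitated]
        times = [r.time_to_recovery_s for r in incap]
        events = [r.recovered for r in incap]
        curve = behavior.km_estimate(times, events)
        medians[temp] = behavior.median_survival(curve)
        quantities.append(
            Quantity(f"recovery_median_{int(temp)}C_s", medians[temp], len(incap))
        )
        if temp == 36.0:
            t_inc = [r.time_to_incapacitation_s for r in records]
            e_inc = [r.incapacitated for r in records]
            inc_curve = behavior.km_estimate(t_inc, e_inc)
            quantities.append(
                Quantity("incapacitation_median_36C_s",
                         behavior.median_survival(inc_curve), n_flies)
            )

    # log-rank separation of channel vs control cohorts at 36 C
    channel = _run_cohort(36.0, 60, seeds[4])
    control = _run_cohort(
        36.0, 60, seeds[5],
        params=synthetic.FlyWalkParams(incap_hazard_max_per_s=0.0),
    )
    res = behavior.logrank_test(
        [r.time_to_incapacitation_s for r in channel],
        [r.incapacitated for r in channel],
        [r.time_to_incapacitation_s for r in control],
        [r.incapacitated for r in control],
    )
    quantities.append(Quantity("logrank_p_36C_channel_vs_control", res.p_value, 120))
    return quantities


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_report(seed: int = 1) -> tuple[list[Quantity], list[Check]]:
    """Compute every reported quantity and evaluate the self-checks."""
    quantities: list[Quantity] = []
    quantities += nernst_quantities()
    quantities += selectivity_quantities()
    quantities += tevc_quantities(seed)
    quantities += calcium_quantities(seed + 1000)
    quantities += behavior_quantities(seed + 2000)

    q = {x.name: x.value for x in quantities}
    checks = [
        Check("nernst_na_printed", abs(q["nernst_na_96_7_mV"] - 69.0) <= 1.0,
              f"computed {q['nernst_na_96_7_mV']:.2f} mV vs printed +69 mV"),
        Check("nernst_k_printed", round(q["nernst_k_2_100_mV"]) == -104,
              f"computed {q['nernst_k_2_100_mV']:.2f} mV vs printed -104 mV"),
        Check("na_fraction_65pct",
              biophysics.percent(q["relative_na_conductance_96_48_pct"] / 100.0) == 65,
              f"computed {q['relative_na_conductance_96_48_pct']:.1f}%"),
        Check("k_fraction_bracket_35_47",
              biophysics.percent(q["relative_k_conductance_lower_pct"] / 100.0) == 35
              and biophysics.percent(q["relative_k_conductance_upper_pct"] / 100.0) == 47,
              f"K bracket {q['relative_k_conductance_lower_pct']:.1f}"
              f"-{q['relative_k_conductance_upper_pct']:.1f}%"),
        Check("ca_remainder_below_10pct", q["relative_ca_conductance_bound_pct"] < 10.0,
              f"bound {q['relative_ca_conductance_bound_pct']:.1f}%"),
        Check("q10_recovery_noiseless",
              abs(q["q10_below_breakpoint"] - 9.05) / 9.05 < 0.01
              and abs(q["q10_above_breakpoint"] - 5.20) / 5.20 < 0.01,
              f"recovered {q['q10_below_breakpoint']:.2f}/{q['q10_above_breakpoint']:.2f} "
              "vs generating 9.05/5.20"),
        Check("q10_breakpoint_on_grid", abs(q["q10_breakpoint_C"] - 20.0) <= 0.25,
              f"breakpoint {q['q10_breakpoint_C']:.2f} C vs generating 20 C"),
        Check("q10_recovery_noisy", q["q10_noisy_recovery_error_pct"] < 10.0,
              f"mean error {q['q10_noisy_recovery_error_pct']:.2f}% at 2% noise"),
        Check("threshold_near_14C", abs(q["activation_threshold_C"] - 14.0) <= 0.5,
              f"detected {q['activation_threshold_C']:.2f} C"),
        Check(
            "lag_slow_vs_fast_channel",
            (
                q["current_temperature_lag_s"]
                > q["current_temperature_lag_fast_channel_s"]
            )
            and 2.0 <= q["current_temperature_lag_s"] <= 8.0,
            f"lag {q['current_temperature_lag_s']:.2f} s (5 s channel tau) vs "
            f"{q['current_temperature_lag_fast_channel_s']:.2f} s (0.5 s tau)",
        ),
        Check("non_inactivating_plateau",
              abs(q["plateau_current_ratio_last_over_first"] - 1.0) < 0.05,
              f"last/first ratio {q['plateau_current_ratio_last_over_first']:.3f}"),
        Check("selectivity_round_trip", q["sim_na_fraction_recovery_error"] < 0.03,
              f"|recovered - generating| = {q['sim_na_fraction_recovery_error']:.4f}"),
        Check("ttest_power_95pct", q["dff_ttest_power_pct"] >= 95.0,
              f"{q['dff_ttest_power_pct']:.1f}% of draws give p < 1e-5"),
        Check("cwt_ridge_one_bin", q["cwt_ridge_error_hz"] <= 1.5 * (32 ** (1 / 47) - 1),
              f"ridge error {q['cwt_ridge_error_hz']:.3f} Hz"),
        Check("dff_sign_consistency", q["dff_sign_consistency_pct"] >= 95.0,
              f"{q['dff_sign_consistency_pct']:.0f}% of seeds give positive dF/F"),
        Check("recovery_order_in_temperature",
              q["recovery_median_34C_s"] < q["recovery_median_36C_s"]
              < q["recovery_median_38C_s"] < q["recovery_median_40C_s"],
              "medians "
              + "/".join(f"{q[f'recovery_median_{t}C_s']:.0f}" for t in (34, 36, 38, 40))
              + " s"),
        Check("logrank_separation", q["logrank_p_36C_channel_vs_control"] < 1e-6,
              f"p = {q['logrank_p_36C_channel_vs_control']:.3g}"),
    ]
    return quantities, checks


def quantities_json(quantities: list[Quantity]) -> dict:
    return {x.name: {"value": float(x.value), "n": int(x.n)} for x in quantities}
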
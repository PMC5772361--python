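"""Synthetic oocyte, calcium-imaging, and heat-box recordings.

Every analysis stage in this package is testable without laboratory data:
these generators produce the three modalities with the statistical structure
the pipelines assume, under parameters that default to the characterized
channel's measured properties.

* :func:`gen_tevc` — voltage-clamp current under a chord-conductance model
  with a piecewise-exponential temperature activation: zero conductance
  below a ~14 C threshold, a steep regime (Q10 ~ 9) up to a ~20 C
  breakpoint, and a shallower regime (Q10 ~ 5) above it, continuous at the
  breakpoint.  Gating carries no voltage dependence and no inactivation —
  a deliberate model restriction mirroring the characterized channel.
* :func:`gen_calcium` — GCaMP-like fluorescence from inhomogeneous Poisson
  events convolved with a fast-rise/slow-decay kernel, with epoch-dependent
  rates driven by the temperature protocol.
* :func:`gen_fly_walks` — reflected random walks in a heat-box chamber with
  a temperature-dependent per-second incapacitation hazard and a
  recovery hazard decreasing with exposure temperature.

Two separate first-order time constants — the bath actuator
(``TemperatureProtocol.bath_tau_s``) and the channel response
(``ChannelParams.channel_tau_s``) — let either hypothesis about the
observed current/temperature lag be emulated, since recordings alone cannot
distinguish them.

All randomness flows from a single seeded generator per call; the seed is
recorded in output metadata, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .biophysics import (
    ND96,
    OOCYTE_INTERNAL,
    STANDARD_VALENCES,
    SolutionComposition,
)
from .calcium import FluorescenceTrace
from .behavior import PositionTrace, CHAMBER_LENGTH_CM
from .tevc import TEVCTrace, IVCurve, iv_from_steps

__all__ = [
    "TemperatureProtocol",
    "ChannelParams",
    "SpikingParams",
    "FlyWalkParams",
    "HeatBoxProtocol",
    "VoltageStep",
    "gen_temperature",
    "gen_tevc",
    "gen_calcium",
    "gen_fly_walks",
    "simulate_iv",
    "WATER_CONTROL",
]


# ---------------------------------------------------------------------------
# temperature protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    kind: str  # "hold" | "ramp"
    duration_s: float
    start_C: float
    end_C: float


@dataclass
class TemperatureProtocol:
    """A sequence of holds and ramps passed through a first-order actuator.

    ``bath_tau_s`` models the thermal inertia of the recording chamber: the
    commanded setpoint is filtered with ``dy/dt = (u - y)/tau``.  Ramp rates
    are limited to 1 C/s (faster commands are not physical for a bath).
    """

    segments: list[_Segment] = field(default_factory=list)
    bath_tau_s: float = 2.0

    def hold(self, duration_s: float, setpoint_C: float) -> "TemperatureProtocol":
        if duration_s <= 0:
            raise ValueError("segment duration must be positive")
        self.segments.append(_Segment("hold", duration_s, setpoint_C, setpoint_C))
        return self

    def ramp(self, start_C: float, end_C: float, rate_C_per_s: float) -> "TemperatureProtocol":
        if not 0 < abs(rate_C_per_s) <= 1.0:
            raise ValueError("ramp rate must be in (0, 1] C/s")
        duration = abs(end_C - start_C) / abs(rate_C_per_s)
        self.segments.append(_Segment("ramp", duration, start_C, end_C))
        return self

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def setpoint(self, time_s: np.ndarray) -> np.ndarray:
        """Commanded setpoint at each time (piecewise hold/linear-ramp)."""
        out = np.empty_like(time_s, dtype=float)
        t0 = 0.0
        if not self.segments:
            raise ValueError("empty protocol")
        for seg in self.segments:
            t1 = t0 + seg.duration_s
            m = (time_s >= t0) & (time_s < t1)
            if seg.kind == "hold":
                out[m] = seg.start_C
            else:
                out[m] = seg.start_C + (seg.end_C - seg.start_C) * (
                    (time_s[m] - t0) / seg.duration_s
                )
            t0 = t1
        out[time_s >= t0] = self.segments[-1].end_C
        return out


def _first_order_filter(u: np.ndarray, dt: float, tau_s: float, y0: float | None = None) -> np.ndarray:
    """Exact discrete solution of dy/dt = (u - y)/tau on a uniform grid."""
    if tau_s <= 0:
        return u.astype(float).copy()
    a = math.exp(-dt / tau_s)
    y = np.empty_like(u, dtype=float)
    y[0] = u[0] if y0 is None else y0
    for i in range(1, u.size):
        y[i] = u[i] + (y[i - 1] - u[i]) * a
    return y


def gen_temperature(
    protocol: TemperatureProtocol, sample_rate_hz: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bath temperature: setpoint sequence filtered by the actuator lag.

    The generator is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    dt = 1.0 / sample_rate_hz
    n = int(round(protocol.duration_s * sample_rate_hz))
    time = np.arange(n) * dt
    setpoint = protocol.setpoint(time)
    temp = _first_order_filter(setpoint, dt, protocol.bath_tau_s)
    return time, temp


# ---------------------------------------------------------------------------
# voltage-clamp currents
# ---------------------------------------------------------------------------

@dataclass
class ChannelParams:
    """Generating parameters of the temperature-gated chord-model channel.

    ``g_max`` is the conductance (uS) at ``reference_temp_C``; ``fractions``
    are chord fractional conductances (sum 1); gating is zero below
    ``threshold_C`` and piecewise-exponential in temperature with
    coefficients ``q10_low`` (threshold..breakpoint) and ``q10_high``
    (above), continuous at ``breakpoint_C``.  ``channel_tau_s`` low-pass
    filters the bath temperature before gating (channel kinetics),
    ``leak_g``/``leak_e`` describe the ohmic background of the cell.
    """

    g_max_uS: float = 1.0
    fractions: dict[str, float] = field(
        default_factory=lambda: {"Na": 0.55, "K": 0.40, "Ca": 0.05}
    )
    threshold_C: float = 14.0
    breakpoint_C: float = 20.0
    q10_low: float = 9.05
    q10_high: float = 5.20
    channel_tau_s: float = 0.5
    leak_g_uS: float = 0.002
    leak_e_mV: float = -30.0
    reference_temp_C: float = 35.0

    def __post_init__(self) -> None:
        if self.q10_low <= 0 or self.q10_high <= 0:
            raise ValueError("Q10 values must be positive")
        if not self.threshold_C < self.breakpoint_C:
            raise ValueError("threshold must lie below the breakpoint")
        if self.g_max_uS > 0 and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    def conductance_uS(self, temperature_C: np.ndarray) -> np.ndarray:
        """Piecewise-exponential gating, scaled so g(reference) = g_max."""
        T = np.asarray(temperature_C, dtype=float)

        def rel(t):
            below = np.minimum(t, self.breakpoint_C)
            above = np.maximum(t, self.breakpoint_C)
            return (
                self.q10_low ** ((below - self.breakpoint_C) / 10.0)
                * self.q10_high ** ((above - self.breakpoint_C) / 10.0)
            )

        g = self.g_max_uS * rel(T) / rel(np.asarray(self.reference_temp_C))
        g = np.where(T < self.threshold_C, 0.0, g)
        return g


#: water-injected control: no channel conductance, leak only
WATER_CONTROL = ChannelParams(g_max_uS=0.0, fractions={})


@dataclass(frozen=True)
class VoltageStep:
    duration_s: float
    voltage_mV: float


def _nernst_series(
    ion: str,
    valence: int,
    c_out: float,
    c_in: float,
    temperature_C: np.ndarray,
) -> np.ndarray:
    # vectorized RT/zF ln ratio with T varying along the trace
    from .biophysics import CELSIUS_OFFSET, FARADAY, GAS_CONSTANT

    tv = GAS_CONSTANT * (np.asarray(temperature_C) + CELSIUS_OFFSET) / FARADAY * 1000.0
    return tv / valence * math.log(c_out / c_in)


def gen_tevc(
    protocol: TemperatureProtocol,
    voltage: float | list[VoltageStep],
    params: ChannelParams = None,
    outside: SolutionComposition = ND96,
    inside: SolutionComposition = OOCYTE_INTERNAL,
    noise_sd_nA: float = 0.0,
    sample_rate_hz: float = 10.0,
    seed: int = 0,
    valences: dict[str, int] | None = None,
) -> TEVCTrace:
    """Simulate a voltage-clamp recording.

    The current is ``g(T_eff) * sum_i f_i (V - E_i) + g_leak (V - E_leak)``
    plus Gaussian noise, with ``T_eff`` the bath temperature low-pass
    filtered by the channel time constant and ``E_i`` the Nernst potentials
    evaluated pointwise at the bath temperature.  Units: uS x mV = nA;
    inward current is negative.
    """
    if params is None:
        params = ChannelParams()
    valences = dict(STANDARD_VALENCES) | (valences or {})
    time, temp = gen_temperature(protocol, sample_rate_hz)
    dt = 1.0 / sample_rate_hz

    if isinstance(voltage, (int, float)):
        v = np.full(time.size, float(voltage))
    else:
        v = np.empty(time.size)
        t0 = 0.0
        for step in voltage:
            m = (time >= t0) & (time < t0 + step.duration_s)
            v[m] = step.voltage_mV
            t0 += step.duration_s
        v[time >= t0] = voltage[-1].voltage_mV

    t_eff = _first_order_filter(temp, dt, params.channel_tau_s)
    g = params.conductance_uS(t_eff)

    drive = np.zeros(time.size)
    for ion, f in params.fractions.items():
        if ion not in outside or ion not in inside:
            raise ValueError(f"solutions missing concentration for permeant ion {ion!r}")
        e_i = _nernst_series(ion, valences[ion], outside[ion], inside[ion], temp)
        drive += f * (v - e_i)

    current = g * drive + params.leak_g_uS * (v - params.leak_e_mV)
    rng = np.random.default_rng(seed)
    if noise_sd_nA > 0:
        current = current + rng.normal(0.0, noise_sd_nA, size=current.size)

    construct = "water-control" if params.g_max_uS == 0 else "channel"
    return TEVCTrace(
        time, current, v, temp, sample_rate_hz,
        metadata={
            "construct": construct,
            "solution": outside.name,
            "seed": seed,
            "generator": "gen_tevc",
        },
    )


def simulate_iv(
    params: ChannelParams,
    outside: SolutionComposition = ND96,
    inside: SolutionComposition = OOCYTE_INTERNAL,
    temperature_C: float = 35.0,
    voltages_mV: np.ndarray | None = None,
    step_s: float = 2.0,
    noise_sd_nA: float = 0.0,
    sample_rate_hz: float = 100.0,
    seed: int = 0,
) -> IVCurve:
    """Voltage-step protocol at a fixed temperature, reduced to an I-V curve."""
    if voltages_mV is None:
        voltages_mV = np.arange(-100.0, 40.0 + 1e-9, 10.0)
    steps = [VoltageStep(step_s, float(vv)) for vv in voltages_mV]
    protocol = TemperatureProtocol(bath_tau_s=0.0).hold(
        step_s * len(steps), temperature_C
    )
    trace = gen_tevc(
        protocol, steps, params, outside, inside, noise_sd_nA, sample_rate_hz, seed
    )
    bounds = [(i * step_s, (i + 1) * step_s) for i in range(len(steps))]
    return iv_from_steps(trace, bounds)


# ---------------------------------------------------------------------------
# calcium fluorescence
# ---------------------------------------------------------------------------

@dataclass
class SpikingParams:
    """Poisson event-train parameters of the fluorescence generator.

    ``rate_low_hz``/``rate_high_hz`` are the event rates at the low/high
    temperature setpoints.  Events are convolved with a
    difference-of-exponentials kernel (rise 0.05 s, decay 0.4 s by default,
    a fast genetically-encoded indicator regime), scaled to
    ``event_amplitude`` at the kernel peak, on top of ``baseline_F`` plus
    linear ``drift`` and Gaussian noise.
    """

    rate_low_hz: float = 1.5
    rate_high_hz: float = 3.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.4
    baseline_F: float = 100.0
    event_amplitude: float = 30.0
    noise_sd: float = 2.0
    drift_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_low_hz < 0 or self.rate_high_hz < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.kernel_rise_s < self.kernel_decay_s:
            raise ValueError("kernel must satisfy 0 < rise < decay")


def control_spiking_params() -> SpikingParams:
    """Control-cell regime: overall activity attenuated at high temperature."""
    return SpikingParams(rate_low_hz=2.0, rate_high_hz=1.2)


def gen_calcium(
    params: SpikingParams,
    protocol: TemperatureProtocol,
    sample_rate_hz: float = 40.0,
    seed: int = 0,
    roi_id: str = "roi0",
    genotype: str = "channel",
) -> FluorescenceTrace:
    """Fluorescence from temperature-switched Poisson events plus noise.

    The instantaneous event rate is ``rate_low`` when the bath temperature
    is below the midpoint of the protocol's temperature range and
    ``rate_high`` above it.
    """
    time, temp = gen_temperature(protocol, sample_rate_hz)
    dt = 1.0 / sample_rate_hz
    rng = np.random.default_rng(seed)

    mid = 0.5 * (temp.min() + temp.max())
    rate = np.where(temp < mid, params.rate_low_hz, params.rate_high_hz)
    events = rng.random(time.size) < rate * dt

    k_t = np.arange(0, 6.0 * params.kernel_decay_s, dt)
    kernel = np.exp(-k_t / params.kernel_decay_s) - np.exp(-k_t / params.kernel_rise_s)
    peak = kernel.max()
    kernel = kernel / peak * params.event_amplitude if peak > 0 else kernel

    f = np.convolve(events.astype(float), kernel)[: time.size]
    f = f + params.baseline_F + params.drift_per_s * time
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=time.size)
    f = np.maximum(f, 0.0)

    return FluorescenceTrace(
        time, f, temp, dt, roi_id=roi_id, genotype=genotype,
        metadata={"seed": seed, "generator": "gen_calcium"},
    )


# ---------------------------------------------------------------------------
# heat-box walks
# ---------------------------------------------------------------------------

@dataclass
class HeatBoxProtocol:
    """Acclimation / exposure / recovery phases of a heat-box trial."""

    test_temp_C: float
    acclimation_s: float = 90.0
    exposure_s: float = 90.0
    recovery_s: float = 1080.0
    baseline_C: float = 24.0
    bath_tau_s: float = 0.5

    def temperature_protocol(self) -> TemperatureProtocol:
        return (
            TemperatureProtocol(bath_tau_s=self.bath_tau_s)
            .hold(self.acclimation_s, self.baseline_C)
            .hold(self.exposure_s, self.test_temp_C)
            .hold(self.recovery_s, self.baseline_C)
        )

    @property
    def exposure_interval_s(self) -> tuple[float, float]:
        return self.acclimation_s, self.acclimation_s + self.exposure_s


@dataclass
class FlyWalkParams:
    """Random-walk and hazard parameters of the heat-box fly generator.

    The walk takes one displacement per second (sd ``step_sd_cm``), pausing
    with probability ``pause_prob``, reflected inside the chamber.  Each
    second the mobile fly incapacitates with a per-second hazard that is a
    logistic function of the current temperature
    (``hazard_max / (1 + exp(-steepness (T - midpoint)))``); once the
    exposure ends, an incapacitated fly recovers each second with a hazard
    that decreases with the exposure temperature, log-interpolated through
    ``recovery_hazard_table``.
    """

    step_sd_cm: float = 1.0
    pause_prob: float = 0.05
    incap_midpoint_C: float = 36.5
    incap_steepness_per_C: float = 1.5
    incap_hazard_max_per_s: float = 0.5
    recovery_hazard_table: dict[float, float] = field(
        default_factory=lambda: {
            34.0: math.log(2) / 20.0,
            36.0: math.log(2) / 162.0,
            38.0: math.log(2) / 383.0,
            40.0: math.log(2) / 760.0,
        }
    )

    def __post_init__(self) -> None:
        if self.step_sd_cm <= 0:
            raise ValueError("step_sd_cm must be positive")
        if not 0 <= self.pause_prob <= 1:
            raise ValueError("pause_prob must be a probability")
        if not 0 <= self.incap_hazard_max_per_s <= 1:
            raise ValueError("per-second hazard ceiling must be in [0, 1]")

    def incapacitation_hazard(self, temperature_C: float) -> float:
        z = self.incap_steepness_per_C * (temperature_C - self.incap_midpoint_C)
        return self.incap_hazard_max_per_s / (1.0 + math.exp(-z))

    def recovery_hazard(self, exposure_temp_C: float) -> float:
        temps = np.array(sorted(self.recovery_hazard_table))
        logs = np.log([self.recovery_hazard_table[t] for t in temps])
        return float(np.exp(np.interp(exposure_temp_C, temps, logs)))


def _reflect(x: float, length: float) -> float:
    period = 2.0 * length
    x = x % period
    return period - x if x > length else x


def gen_fly_walks(
    params: FlyWalkParams,
    n_flies: int,
    protocol: HeatBoxProtocol,
    sample_rate_hz: float = 5.0,
    seed: int = 0,
    genotype: str = "channel",
    chamber_length_cm: float = CHAMBER_LENGTH_CM,
) -> list[PositionTrace]:
    """Simulate heat-box position traces for a cohort of flies.

    Incapacitated flies freeze in place; recovery (walk resumption) can only
    begin once the exposure phase has ended.  Each fly draws from an
    independent stream spawned from ``seed``.
    """
    if n_flies < 1:
        raise ValueError("need at least one fly")
    temp_protocol = protocol.temperature_protocol()
    # per-second temperature grid drives the hazards
    sec_time = np.arange(int(round(temp_protocol.duration_s)))
    sec_temp = temp_protocol.setpoint(sec_time.astype(float))
    e0, e1 = protocol.exposure_interval_s
    h_rec = params.recovery_hazard(protocol.test_temp_C)

    n_sec = sec_time.size
    h_incap = np.array([params.incapacitation_hazard(float(T)) for T in sec_temp])
    streams = np.random.SeedSequence(seed).spawn(n_flies)
    traces: list[PositionTrace] = []
    for fid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        start = rng.uniform(0, chamber_length_cm)
        steps = rng.normal(0.0, params.step_sd_cm, n_sec)
        u_state = rng.random(n_sec)
        u_pause = rng.random(n_sec)
        pos = np.empty(n_sec)
        pos[0] = start
        frozen = False
        for k in range(1, n_sec):
            if frozen:
                if sec_time[k] >= e1 and u_state[k] < h_rec:
                    frozen = False
            elif u_state[k] < h_incap[k]:
                frozen = True
            if frozen or u_pause[k] < params.pause_prob:
                pos[k] = pos[k - 1]
            else:
                pos[k] = _reflect(pos[k - 1] + steps[k], chamber_length_cm)
        # upsample to the recording rate
        time = np.arange(0.0, n_sec - 1.0 + 1e-9, 1.0 / sample_rate_hz)
        position = np.interp(time, sec_time.astype(float), pos)
        temperature = np.interp(time, sec_time.astype(float), sec_temp)
        traces.append(
            PositionTrace(
                time, position, temperature,
                fly_id=f"fly{fid:03d}", genotype=genotype,
                chamber_length_cm=chamber_length_cm,
                metadata={"seed": seed, "test_temp_C": protocol.test_temp_C,
                          "generator": "gen_fly_walks"},
            )
        )
    return traces
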
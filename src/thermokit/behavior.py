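"""Heat-box behavior analysis: incapacitation calling and survival analysis.

A fly walks a narrow heated chamber while a sensor records its position.
During a timed exposure to an elevated temperature, the fly is called
*incapacitated* if it accumulates at least 45 s of inactivity within a 90 s
window (a sample counts as inactive when the position moved less than a
small threshold over the preceding second).  Times to incapacitation and to
recovery — with right-censoring at the end of the exposure or of the
recovery observation — feed a Kaplan-Meier product-limit analysis, with
two-group comparison by the log-rank test.

The 45-in-90 criterion is read as *cumulative* inactivity within a sliding
window by default; a contiguous-run reading is available for sensitivity
analysis (``mode="contiguous"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "PositionTrace",
    "EventRecord",
    "SurvivalCurve",
    "LogrankResult",
    "detect_incapacitation",
    "events_to_frame",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "incapacitation_by_temperature",
    "infer_exposure",
]

CHAMBER_LENGTH_CM = 3.4
RECOVERY_HORIZON_S = 1080.0


class AnalysisError(ValueError):
    pass


@dataclass
class PositionTrace:
    """Fly position along the chamber plus the temperature protocol."""

    time_s: np.ndarray
    position_cm: np.ndarray
    temperature_C: np.ndarray
    fly_id: str = "fly0"
    genotype: str = "control"
    chamber_length_cm: float = CHAMBER_LENGTH_CM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_cm = np.asarray(self.position_cm, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        n = self.time_s.size
        if self.position_cm.size != n or self.temperature_C.size != n:
            raise AnalysisError("all channels must share the time base")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise AnalysisError("time must be strictly increasing")
        eps = 1e-9
        if np.any(self.position_cm < -eps) or np.any(
            self.position_cm > self.chamber_length_cm + eps
        ):
            raise AnalysisError(
                f"position outside chamber bounds [0, {self.chamber_length_cm}] cm"
            )


@dataclass
class EventRecord:
    """Per-fly incapacitation/recovery calls with censoring."""

    fly_id: str
    genotype: str
    exposure_temperature_C: float
    incapacitated: bool
    time_to_incapacitation_s: float  # censoring time when not incapacitated
    incapacitation_censored: bool
    recovered: bool
    time_to_recovery_s: float | None  # None for flies never incapacitated
    recovery_censored: bool


def infer_exposure(trace: PositionTrace) -> tuple[float, float]:
    """Longest contiguous run at the warm half of the temperature range.

    Returns a half-open interval ``(start, end)``: ``end`` is the time of
    the first sample after the hot run (or the last sample time when the
    run reaches the end of the trace), so an exposure commanded for N
    seconds is reported as N seconds long.
    """
    temp = trace.temperature_C
    mid = temp.min() + 0.5 * (temp.max() - temp.min())
    hot = temp >= mid
    if not hot.any():
        raise AnalysisError("no elevated-temperature period found")
    edges = np.flatnonzero(np.diff(hot.astype(int)))
    starts = [0] if hot[0] else []
    starts += list(edges[hot[edges + 1]] + 1)
    ends = list(edges[~hot[edges + 1]] + 1) + ([hot.size] if hot[-1] else [])
    runs = [(s, e) for s, e in zip(starts, ends)]
    s, e = max(runs, key=lambda r: r[1] - r[0])
    end_idx = min(e, trace.time_s.size - 1)
    return float(trace.time_s[s]), float(trace.time_s[end_idx])


def _first_qualifying_run_start(inactive: np.ndarray, w0: int, w1: int) -> int:
    """Index of the first inactive run inside the window [w0, w1)."""
    for i in range(w0, w1):
        if inactive[i] and (i == 0 or not inactive[i - 1]):
            return i
        if inactive[i] and i == w0:
            # run may have started before the window; walk back
            j = i
            while j > 0 and inactive[j - 1]:
                j -= 1
            return j
    raise AnalysisError("window qualified without any inactive sample")


def detect_incapacitation(
    trace: PositionTrace,
    exposure_s: tuple[float, float] | None = None,
    window_s: float = 90.0,
    inactive_s: float = 45.0,
    motion_eps_cm: float = 0.1,
    mode: str = "cumulative",
    recovery_sustained_s: float = 5.0,
    recovery_horizon_s: float = RECOVERY_HORIZON_S,
) -> EventRecord:
    """Call incapacitation and recovery for one fly.

    The position is resampled to a 1 s grid; second ``i`` is inactive when
    the position moved less than ``motion_eps_cm`` between seconds ``i-1``
    and ``i``.  The fly is incapacitated if some 90 s window (1 s stride)
    inside the exposure contains at least 45 s of inactivity — cumulative
    seconds by default, one contiguous run with ``mode="contiguous"``.  The
    time to incapacitation is the start (relative to exposure onset) of the
    earliest inactive run inside the first qualifying window.  For
    incapacitated flies, recovery is the first sustained
    (``recovery_sustained_s``) movement after the exposure ends, censored at
    ``recovery_horizon_s``.
    """
    if mode not in ("cumulative", "contiguous"):
        raise AnalysisError(f"unknown mode {mode!r}")
    if motion_eps_cm <= 0:
        raise AnalysisError("motion_eps_cm must be positive")
    if exposure_s is None:
        exposure_s = infer_exposure(trace)
    e0, e1 = exposure_s
    if e1 - e0 < window_s - 1e-9:
        raise AnalysisError(
            f"exposure ({e1 - e0:.0f} s) shorter than the {window_s:.0f} s window"
        )
    if trace.time_s[0] > e0 or trace.time_s[-1] < e1:
        raise AnalysisError("trace does not cover the exposure window")

    # 1 s grid over the full trace
    grid = np.arange(np.ceil(trace.time_s[0]), np.floor(trace.time_s[-1]) + 1.0)
    pos = np.interp(grid, trace.time_s, trace.position_cm)
    inactive = np.zeros(grid.size, dtype=bool)
    inactive[1:] = np.abs(np.diff(pos)) < motion_eps_cm

    w = int(round(window_s))
    need = int(round(inactive_s))
    gi0 = int(np.searchsorted(grid, e0, side="left"))
    gi1 = int(np.searchsorted(grid, e1, side="right"))

    exposure_duration = e1 - e0
    incapacitated = False
    t_incap = exposure_duration  # censoring time if never incapacitated
    first_window: tuple[int, int] | None = None

    for s in range(gi0, gi1 - w + 1):
        window = inactive[s + 1: s + w + 1]  # seconds (s, s+w]
        if mode == "cumulative":
            ok = int(window.sum()) >= need
        else:
            runs = np.diff(
                np.flatnonzero(
                    np.diff(np.concatenate(([0], window.astype(int), [0])))
                ).reshape(-1, 2),
                axis=1,
            )
            ok = runs.size > 0 and int(runs.max()) >= need
        if ok:
            incapacitated = True
            first_window = (s + 1, min(s + w + 1, gi1))
            break

    if incapacitated and first_window is not None:
        run_start = _first_qualifying_run_start(inactive, *first_window)
        t_incap = float(grid[run_start] - e0)
        t_incap = max(0.0, t_incap)

    recovered = False
    recovery_censored = False
    t_recovery: float | None = None
    if incapacitated:
        sustain = int(round(recovery_sustained_s))
        horizon_idx = int(np.searchsorted(grid, e1 + recovery_horizon_s, side="right"))
        active = ~inactive
        found = None
        for i in range(gi1, min(horizon_idx, grid.size) - sustain + 1):
            if np.all(active[i: i + sustain]):
                found = i
                break
        if found is not None:
            recovered = True
            t_recovery = float(grid[found] - e1)
        else:
            recovery_censored = True
            t_recovery = float(min(recovery_horizon_s, grid[-1] - e1))

    return EventRecord(
        fly_id=trace.fly_id,
        genotype=trace.genotype,
        exposure_temperature_C=float(
            np.median(trace.temperature_C[(trace.time_s >= e0) & (trace.time_s <= e1)])
        ),
        incapacitated=incapacitated,
        time_to_incapacitation_s=t_incap,
        incapacitation_censored=not incapacitated,
        recovered=recovered,
        time_to_recovery_s=t_recovery,
        recovery_censored=recovery_censored,
    )


def events_to_frame(records: list[EventRecord]) -> pd.DataFrame:
    """Event table as a DataFrame (one row per fly)."""
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``survival[i]`` is S(t) for t in [times[i], times[i+1]); times include 0
    with S(0) = 1.  ``variance`` is the Greenwood estimate at each time.
    """

    times_s: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray | None = None

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times_s, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def summary(self) -> str:
        lines = ["Kaplan-Meier survival estimate", "  t(s)    S(t)    at risk"]
        for t, s, n in zip(self.times_s, self.survival, self.at_risk):
            lines.append(f"  {t:7.1f} {s:6.3f} {int(n):8d}")
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.times_s, self.survival, where="post", **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(times_s, event_observed) -> SurvivalCurve:
    """Product-limit survival estimate with right-censoring.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times
    ``t_i`` with ``d_i`` events among ``n_i`` at risk; censored observations
    leave the risk set without contributing events.
    """
    times = np.asarray(times_s, dtype=float)
    events = np.asarray(event_observed, dtype=bool)
    if times.size == 0:
        raise AnalysisError("empty survival input")
    if np.any(times < 0):
        raise AnalysisError("times must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    table = kmf.event_table
    at_risk_map = table["at_risk"].to_dict()
    n_total = times.size
    at_risk = np.array([at_risk_map.get(t, n_total) for t in timeline], dtype=float)

    # Greenwood variance: S(t)^2 * sum d_i / (n_i (n_i - d_i))
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
    cum = np.cumsum(term)
    var_map = dict(zip(table.index.to_numpy(dtype=float), cum))
    running = 0.0
    var = np.empty_like(surv)
    for j, t in enumerate(timeline):
        running = var_map.get(t, running)
        var[j] = surv[j] ** 2 * running

    if timeline[0] != 0.0:
        timeline = np.insert(timeline, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
        at_risk = np.insert(at_risk, 0, n_total)
        var = np.insert(var, 0, 0.0)
    return SurvivalCurve(timeline, surv, at_risk, var)


def median_survival(curve: SurvivalCurve) -> float:
    """Earliest time with S(t) <= 0.5, or NaN when S never reaches 0.5."""
    below = np.flatnonzero(curve.survival <= 0.5)
    if below.size == 0:
        return float("nan")
    return float(curve.times_s[below[0]])


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float

    def summary(self) -> str:
        return f"log-rank test: chi2 = {self.chi2:.4f}, p = {self.p_value:.3g}"


def logrank_test(
    times_a, events_a, times_b, events_b
) -> LogrankResult:
    """Two-group log-rank test over the pooled event times.

    This is the standard comparison associated with Kaplan-Meier curves.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise AnalysisError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise AnalysisError("no events in either group; log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def incapacitation_by_temperature(events: pd.DataFrame) -> pd.Series:
    """Cumulative proportion of flies never incapacitated, by temperature.

    ``events`` holds one row per (fly, temperature step) with columns
    ``fly_id``, ``exposure_temperature_C`` and ``incapacitated``; the same
    cohort is assumed to be stepped through increasing temperatures.  The
    returned series maps each tested temperature to the fraction of flies
    whose first incapacitation occurred above it; it is non-increasing.
    """
    required = {"fly_id", "exposure_temperature_C", "incapacitated"}
    if not required.issubset(events.columns):
        raise AnalysisError(f"events frame must have columns {sorted(required)}")
    temps = np.sort(events["exposure_temperature_C"].unique())
    n_flies = events["fly_id"].nunique()
    first_incap = (
        events[events["incapacitated"]]
        .groupby("fly_id")["exposure_temperature_C"]
        .min()
    )
    frac = [
        1.0 - float((first_incap <= t).sum()) / n_flies
        for t in temps
    ]
    return pd.Series(frac, index=temps, name="fraction_not_incapacitated")
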
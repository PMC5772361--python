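"""Analysis of two-electrode voltage-clamp recordings.

Operations on temperature-ramp and voltage-step current recordings from a
temperature-gated, voltage-insensitive channel:

* reversal potential by zero-crossing interpolation of an I-V curve;
* two-regime temperature-coefficient (Q10) estimation from slow ramps,
  via an exhaustive breakpoint grid search over two independent
  least-squares lines in log10(normalized current) vs temperature,
  with Q10 = 10**(10*s) for a slope s per degree Celsius;
* activation-threshold detection against the sub-threshold baseline;
* cross-correlation lag between current and bath temperature.

Current sign convention: inward current is negative; magnitudes are used for
normalization and fitting after baseline subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TEVCTrace",
    "IVCurve",
    "ReversalEstimate",
    "Q10Fit",
    "LagEstimate",
    "estimate_reversal",
    "normalize_current",
    "fit_q10",
    "detect_threshold",
    "xcorr_lag",
    "iv_from_steps",
    "TemperatureSensitivityModel",
    "TemperatureSensitivityResults",
]


class AnalysisError(ValueError):
    """Raised when a trace does not support the requested estimate."""


@dataclass
class TEVCTrace:
    """A voltage-clamp recording: time, current, command voltage, temperature.

    All channels are sampled on the same uniform time base.  ``metadata``
    carries the construct label (channel-expressing vs water control), the
    solution name, and any generator provenance.
    """

    time_s: np.ndarray
    current_nA: np.ndarray
    voltage_mV: np.ndarray
    temperature_C: np.ndarray
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        n = self.time_s.size
        for name in ("current_nA", "voltage_mV", "temperature_C"):
            if getattr(self, name).size != n:
                raise AnalysisError(f"channel {name} length != time length {n}")
        if not self.sample_rate_hz > 0:
            raise AnalysisError("sample_rate_hz must be positive")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise AnalysisError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size

    def window(self, t0: float, t1: float) -> "TEVCTrace":
        """Sub-trace restricted to ``t0 <= t <= t1``."""
        m = (self.time_s >= t0) & (self.time_s <= t1)
        return TEVCTrace(
            self.time_s[m], self.current_nA[m], self.voltage_mV[m],
            self.temperature_C[m], self.sample_rate_hz, dict(self.metadata),
        )


@dataclass
class IVCurve:
    """Steady-state current at each command voltage, at one temperature."""

    voltages_mV: np.ndarray
    currents_nA: np.ndarray
    temperature_C: float
    sem_nA: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_nA = np.asarray(self.currents_nA, dtype=float)
        if self.voltages_mV.size != self.currents_nA.size:
            raise AnalysisError("voltages and currents must have equal length")
        if self.voltages_mV.size > 1 and not np.all(np.diff(self.voltages_mV) > 0):
            raise AnalysisError("voltages must be strictly increasing")


@dataclass(frozen=True)
class ReversalEstimate:
    """Zero-current crossing of an I-V curve."""

    erev_mV: float
    width_mV: float  # spacing of the bracketing voltage interval
    ambiguous: bool = False  # more than one sign change observed


@dataclass(frozen=True)
class LagEstimate:
    """Lag of current behind temperature; positive = current follows."""

    lag_s: float
    peak_correlation: float


@dataclass
class Q10Fit:
    """Two-regime temperature-sensitivity fit.

    ``q10_low``/``q10_high`` are the temperature coefficients below and above
    ``breakpoint_C``, each ``10**(10*slope)`` for the slope of the
    least-squares line through log10(normalized current) vs temperature over
    the corresponding range in ``fit_ranges``.
    """

    breakpoint_C: float
    slope_low: float
    slope_high: float
    q10_low: float
    q10_high: float
    threshold_C: float
    fit_ranges: tuple[tuple[float, float], tuple[float, float]]
    r2_low: float
    r2_high: float
    single_regime: bool = False
    sse: float = float("nan")


def estimate_reversal(iv: IVCurve) -> ReversalEstimate:
    """Reversal potential by linear interpolation at the zero crossing.

    If the current changes sign more than once (noise near zero), the
    crossing closest to the median command voltage is returned and the
    estimate is flagged ambiguous.  A curve that never changes sign has no
    reversal in range and raises.
    """
    v, i = iv.voltages_mV, iv.currents_nA
    if v.size < 2:
        raise AnalysisError("need at least two I-V points")

    crossings: list[tuple[float, float]] = []  # (erev, width)
    for k in range(v.size - 1):
        i0, i1 = i[k], i[k + 1]
        if i0 == 0.0:
            crossings.append((float(v[k]), 0.0))
        elif i0 * i1 < 0:
            erev = v[k] + (v[k + 1] - v[k]) * (-i0) / (i1 - i0)
            crossings.append((float(erev), float(v[k + 1] - v[k])))
    if i[-1] == 0.0:
        crossings.append((float(v[-1]), 0.0))

    if not crossings:
        raise AnalysisError(
            "no reversal in range: current spans "
            f"[{i.min():.3g}, {i.max():.3g}] nA without a sign change"
        )
    if len(crossings) == 1:
        erev, width = crossings[0]
        return ReversalEstimate(erev, width, ambiguous=False)
    vmed = float(np.median(v))
    erev, width = min(crossings, key=lambda c: abs(c[0] - vmed))
    return ReversalEstimate(erev, width, ambiguous=True)


def _reference_mask_near_max_temp(trace: TEVCTrace, margin_C: float = 0.25) -> np.ndarray:
    tmax = float(np.max(trace.temperature_C))
    return np.abs(trace.temperature_C - tmax) <= margin_C


def normalize_current(
    trace: TEVCTrace,
    reference: Callable[[TEVCTrace], np.ndarray] | np.ndarray | None = None,
) -> np.ndarray:
    """|current| divided by its mean magnitude over a reference selection.

    ``reference`` is a boolean mask (or a callable producing one); by default
    the samples within 0.25 degrees C of the ramp's maximum temperature.
    """
    if reference is None:
        mask = _reference_mask_near_max_temp(trace)
    elif callable(reference):
        mask = np.asarray(reference(trace), dtype=bool)
    else:
        mask = np.asarray(reference, dtype=bool)
    if not mask.any():
        raise AnalysisError("empty reference selection for normalization")
    ref = float(np.mean(np.abs(trace.current_nA[mask])))
    if ref == 0.0:
        raise AnalysisError("reference current magnitude is zero")
    return np.abs(trace.current_nA) / ref


def _segment_ols(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """(Weighted) least-squares line; returns (slope, intercept, sse, r2).

    With additive recording noise on the current, the log-transformed points
    have noise inversely proportional to the signal; weights proportional to
    the squared signal make the log-space fit equivalent to a Gauss-Newton
    step of the maximum-likelihood exponential fit.
    """
    slope, intercept = np.polyfit(x, y, 1, w=None if w is None else np.sqrt(w))
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    return float(slope), float(intercept), sse, r2


def fit_q10(
    trace: TEVCTrace,
    ramp_window: tuple[float, float] | None = None,
    threshold_C: float = 14.0,
    baseline: float | str = "auto",
    grid_resolution_C: float = 0.25,
    min_samples_per_segment: int = 10,
    fit_margin_C: float = 0.5,
    presmooth_s: float = 20.0,
    breakpoint_gap_C: float = 1.0,
    noise_floor_k: float = 3.0,
) -> Q10Fit:
    """Two-regime Q10 fit from a slow monotone temperature ramp.

    Procedure: (1) subtract the baseline current (mean below the activation
    threshold, or an explicit value); (2) normalize the magnitude to its mean
    near the maximum ramp temperature and take log10; (3) grid-search the
    breakpoint between ``threshold_C + 2`` and ``Tmax - 2`` at
    ``grid_resolution_C`` steps, scoring each candidate by the SSE of a
    continuity-constrained two-slope (hinge) fit over all valid points;
    (4) refit each regime as its own *independent* least-squares line on the
    disjoint ranges either side of the breakpoint gap and convert each slope
    to a Q10.  If the two slopes agree within 2% the data are flagged as a
    single temperature-sensitivity regime.

    ``fit_margin_C`` trims the first fraction of a degree above threshold
    from the fit: right at threshold the current is still emerging from the
    baseline (actuator and channel lag), and its logarithm is dominated by
    baseline residuals there.  ``presmooth_s`` applies a centered moving
    average to the baseline-subtracted current before the log transform;
    on a slow ramp this spans a fraction of a degree and leaves the
    log-slope of an exponential unchanged, while keeping recording noise
    from biasing the logarithm where the current is still small.  Samples
    whose smoothed magnitude stays within ``noise_floor_k`` standard errors
    of the noise (estimated from the high-frequency residual) are excluded,
    and ``breakpoint_gap_C`` degrees on either side of each candidate
    breakpoint are left out of both segments so the smeared kink region
    never biases the slopes — the two fitted ranges are disjoint.
    """
    sub = trace if ramp_window is None else trace.window(*ramp_window)
    temp = sub.temperature_C
    if temp.size < 2 * min_samples_per_segment:
        raise AnalysisError("too few samples in the ramp window")
    dT = np.diff(temp)
    if not (np.all(dT >= 0) or np.all(dT <= 0)):
        raise AnalysisError("temperature is not monotone within the ramp window")
    tmax = float(temp.max())
    if tmax - threshold_C < 8.0:
        raise AnalysisError(
            f"ramp spans only {tmax - threshold_C:.1f} C above threshold; need >= 8 C"
        )

    if baseline == "auto":
        below = temp < threshold_C - 0.5
        base = float(np.mean(sub.current_nA[below])) if below.any() else 0.0
    else:
        base = float(baseline)
    centered = sub.current_nA - base
    # noise level from the high-frequency residual of a short moving average
    sigma_raw = float(np.std(centered - _moving_average(centered, 5)))
    if sigma_raw <= 1e-12 * max(float(np.abs(centered).max()), 1.0):
        width = 1  # noiseless data: smoothing would only add edge bias
    else:
        width = max(1, int(round(presmooth_s * sub.sample_rate_hz)))
    smoothed = _moving_average(centered, width)
    adj = np.abs(smoothed)
    floor = noise_floor_k * sigma_raw / np.sqrt(width)

    above = temp >= threshold_C + fit_margin_C
    if not above.any():
        raise AnalysisError("no samples above the activation threshold")
    ref_mask = above & (np.abs(temp - tmax) <= 0.25)
    ref = float(np.mean(adj[ref_mask]))
    if ref == 0.0:
        raise AnalysisError("zero current at the normalization reference")
    norm = adj / ref
    valid = above & (norm > 0) & (adj > floor)
    if width > 1:
        # the centered average is edge-padded within half a window of the
        # trace ends; drop those samples rather than fit their bias
        idx = np.arange(temp.size)
        valid &= (idx >= width // 2) & (idx < temp.size - width // 2)
    x = temp[valid]
    y = np.log10(norm[valid])
    weights = norm[valid] ** 2

    lo_edge, hi_edge = threshold_C + 2.0, tmax - 2.0
    if hi_edge <= lo_edge:
        raise AnalysisError("ramp too short for a breakpoint search")
    grid = np.arange(lo_edge, hi_edge + 1e-9, grid_resolution_C)

    # Stage 1: locate the breakpoint with a continuity-constrained two-slope
    # fit over *all* valid points.  Fitting both segments jointly through a
    # shared hinge keeps the SSE comparable across candidates; independent
    # per-segment fits would favour degenerate breakpoints whose short
    # segment contributes almost no residual.
    # A regime whose valid data span less than ``min_extent_C`` cannot pin
    # down a slope; such breakpoints are not identifiable and are skipped.
    min_extent_C = 2.0
    best: tuple[float, float] | None = None
    for bp_c in grid:
        left = np.minimum(x - bp_c, 0.0)
        right = np.maximum(x - bp_c, 0.0)
        design = np.column_stack([np.ones_like(x), left, right])
        lo_pts = x[left < 0]
        hi_pts = x[right > 0]
        if lo_pts.size < min_samples_per_segment or hi_pts.size < min_samples_per_segment:
            continue
        # each *refit* segment (outside the breakpoint gap) must span enough
        # temperature to pin down a slope
        if (bp_c - breakpoint_gap_C) - lo_pts.min() < min_extent_C:
            continue
        if hi_pts.max() - (bp_c + breakpoint_gap_C) < min_extent_C:
            continue
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse_c = float(resid @ resid)
        if best is None or sse_c < best[0]:
            best = (sse_c, bp_c)
    if best is None:
        raise AnalysisError(
            f"fewer than {min_samples_per_segment} samples per segment at every "
            "candidate breakpoint"
        )
    bp = best[1]

    # Stage 2: refit each regime's slope on its own range, leaving a gap of
    # ``breakpoint_gap_C`` around the breakpoint so the pre-smoothing smear
    # of the kink does not bias either Q10.
    lo_m = x <= bp - breakpoint_gap_C
    hi_m = x > bp + breakpoint_gap_C
    if lo_m.sum() < min_samples_per_segment or hi_m.sum() < min_samples_per_segment:
        raise AnalysisError(
            "too few samples left in a regime after excluding the breakpoint gap"
        )
    fit_lo = _segment_ols(x[lo_m], y[lo_m], weights[lo_m])
    fit_hi = _segment_ols(x[hi_m], y[hi_m], weights[hi_m])
    sse = fit_lo[2] + fit_hi[2]
    slope_low, _, _, r2_low = fit_lo
    slope_high, _, _, r2_high = fit_hi
    q10_low = 10.0 ** (10.0 * slope_low)
    q10_high = 10.0 ** (10.0 * slope_high)

    rel_slope_gap = abs(slope_low - slope_high) / max(abs(slope_low), abs(slope_high), 1e-12)
    single = rel_slope_gap < 0.02

    return Q10Fit(
        breakpoint_C=float(bp),
        slope_low=slope_low,
        slope_high=slope_high,
        q10_low=q10_low,
        q10_high=q10_high,
        threshold_C=threshold_C,
        fit_ranges=(
            (threshold_C + fit_margin_C, float(bp) - breakpoint_gap_C),
            (float(bp) + breakpoint_gap_C, tmax),
        ),
        r2_low=r2_low,
        r2_high=r2_high,
        single_regime=single,
        sse=float(sse),
    )


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad: pad + x.size]
    return out


def detect_threshold(
    trace: TEVCTrace,
    k: float = 3.0,
    smooth_s: float = 1.0,
    baseline_span_C: float = 2.0,
    sustain_C: float = 1.0,
) -> float:
    """Activation threshold: where smoothed |current| leaves the baseline.

    The baseline is taken from the samples within ``baseline_span_C`` of the
    coldest temperature reached.  The threshold is the lowest temperature at
    which the smoothed current magnitude exceeds baseline mean + ``k`` SD and
    stays above that criterion for at least ``sustain_C`` degrees of further
    ramp.
    """
    temp = trace.temperature_C
    width = max(1, int(round(smooth_s * trace.sample_rate_hz)))
    smoothed = _moving_average(np.abs(trace.current_nA), width)

    tmin = float(temp.min())
    base_mask = temp <= tmin + baseline_span_C
    if not base_mask.any():
        raise AnalysisError("no baseline samples at the cold end of the trace")
    crit = float(smoothed[base_mask].mean() + k * smoothed[base_mask].std())

    above = smoothed > crit
    candidates = np.flatnonzero(above)
    if candidates.size == 0:
        raise AnalysisError("no activation detected: current never exceeds baseline criterion")

    for idx in candidates:
        t0 = temp[idx]
        sustain = (temp >= t0) & (temp <= t0 + sustain_C)
        if sustain.any() and np.all(above[sustain]):
            return float(t0)
    raise AnalysisError("no activation detected: criterion never sustained")


def xcorr_lag(trace: TEVCTrace, max_lag_s: float, use_abs: bool = True) -> LagEstimate:
    """Lag maximizing the normalized cross-correlation of current vs temperature.

    Positive lag means the current follows the temperature.  Both channels
    are mean-removed; the current enters as a magnitude by default (inward
    currents are negative).  The discrete peak is refined by a parabolic fit
    through its two neighbors.
    """
    fs = trace.sample_rate_hz
    max_lag = int(round(max_lag_s * fs))
    n = len(trace)
    if n < 2 * max_lag + 2:
        raise AnalysisError("trace shorter than twice the maximum lag")

    cur = np.abs(trace.current_nA) if use_abs else trace.current_nA.astype(float)
    cur = cur - cur.mean()
    tmp = trace.temperature_C - trace.temperature_C.mean()
    if np.allclose(cur, 0) or np.allclose(tmp, 0):
        raise AnalysisError("correlation undefined: a channel is constant")

    full = np.correlate(cur, tmp, mode="full")  # index n-1+k ~ sum tmp[t]*cur[t+k]
    norm = np.sqrt(float(cur @ cur) * float(tmp @ tmp))
    lags = np.arange(-max_lag, max_lag + 1)
    r = full[n - 1 + lags] / norm

    j = int(np.argmax(r))
    lag = float(lags[j])
    peak = float(r[j])
    if 0 < j < r.size - 1:
        y0, y1, y2 = r[j - 1], r[j], r[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * (y0 - y2) / denom
    return LagEstimate(lag_s=lag / fs, peak_correlation=min(1.0, max(-1.0, peak)))


def iv_from_steps(
    trace: TEVCTrace,
    step_bounds_s: Sequence[tuple[float, float]],
    steady_fraction: float = 0.2,
) -> IVCurve:
    """Summarize a voltage-step recording into an I-V curve.

    The steady-state current per step is the mean over the final
    ``steady_fraction`` of the step's duration.  Steps are identified by the
    (start, end) times in ``step_bounds_s``.
    """
    volts, currents, sems = [], [], []
    for t0, t1 in step_bounds_s:
        t_from = t1 - steady_fraction * (t1 - t0)
        m = (trace.time_s >= t_from) & (trace.time_s < t1)
        if not m.any():
            raise AnalysisError(f"no samples in the steady window of step [{t0}, {t1}] s")
        volts.append(float(trace.voltage_mV[m].mean()))
        currents.append(float(trace.current_nA[m].mean()))
        sems.append(float(trace.current_nA[m].std(ddof=1) / np.sqrt(m.sum())) if m.sum() > 1 else 0.0)
    order = np.argsort(volts)
    return IVCurve(
        voltages_mV=np.asarray(volts)[order],
        currents_nA=np.asarray(currents)[order],
        temperature_C=float(trace.temperature_C.mean()),
        sem_nA=np.asarray(sems)[order],
    )


class TemperatureSensitivityModel:
    """Two-regime Q10 model of a temperature-ramp recording.

    Thin statsmodels-style wrapper: the model holds the trace and fitting
    choices, ``fit`` runs :func:`fit_q10` plus threshold detection, and the
    results object carries the estimates with a ``summary`` table.
    """

    def __init__(
        self,
        trace: TEVCTrace,
        ramp_window: tuple[float, float] | None = None,
        threshold_C: float | None = None,
        **fit_kwargs,
    ) -> None:
        self.trace = trace
        self.ramp_window = ramp_window
        self.threshold_C = threshold_C
        self.fit_kwargs = fit_kwargs

    def fit(self) -> "TemperatureSensitivityResults":
        if self.threshold_C is None:
            try:
                threshold = detect_threshold(self.trace)
            except AnalysisError:
                threshold = 14.0
        else:
            threshold = self.threshold_C
        q10 = fit_q10(
            self.trace, self.ramp_window, threshold_C=threshold, **self.fit_kwargs
        )
        return TemperatureSensitivityResults(self, q10, threshold)


class TemperatureSensitivityResults:
    def __init__(
        self, model: TemperatureSensitivityModel, fit: Q10Fit, threshold_C: float
    ) -> None:
        self.model = model
        self.q10_fit = fit
        self.threshold_C = threshold_C

    @property
    def params(self) -> dict[str, float]:
        f = self.q10_fit
        return {
            "threshold_C": self.threshold_C,
            "breakpoint_C": f.breakpoint_C,
            "q10_low": f.q10_low,
            "q10_high": f.q10_high,
        }

    def summary(self) -> str:
        f = self.q10_fit
        lines = [
            "Two-regime temperature sensitivity (Q10) fit",
            f"  activation threshold : {self.threshold_C:6.2f} C",
            f"  regime breakpoint    : {f.breakpoint_C:6.2f} C",
            f"  Q10 below breakpoint : {f.q10_low:6.2f}  "
            f"(slope {f.slope_low:.4f}/C, R2 {f.r2_low:.4f}, "
            f"{f.fit_ranges[0][0]:.1f}-{f.fit_ranges[0][1]:.1f} C)",
            f"  Q10 above breakpoint : {f.q10_high:6.2f}  "
            f"(slope {f.slope_high:.4f}/C, R2 {f.r2_high:.4f}, "
            f"{f.fit_ranges[1][0]:.1f}-{f.fit_ranges[1][1]:.1f} C)",
        ]
        if f.single_regime:
            lines.append("  note: slopes agree within 2% -- single regime")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: log10 normalized current vs temperature with fits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = (
            self.model.trace
            if self.model.ramp_window is None
            else self.model.trace.window(*self.model.ramp_window)
        )
        norm = normalize_current(trace)
        mask = (trace.temperature_C >= self.threshold_C) & (norm > 0)
        ax.plot(trace.temperature_C[mask], np.log10(norm[mask]), ".", ms=2, alpha=0.5)
        f = self.q10_fit
        for (t0, t1), slope in (
            (f.fit_ranges[0], f.slope_low),
            (f.fit_ranges[1], f.slope_high),
        ):
            tt = np.linspace(t0, t1, 20)
            mid_m = (trace.temperature_C >= t0) & (trace.temperature_C <= t1) & (norm > 0)
            if mid_m.any():
                # anchor the drawn line at the segment's own mean point
                ym = np.log10(norm[mid_m]).mean()
                tm = trace.temperature_C[mid_m].mean()
                ax.plot(tt, ym + slope * (tt - tm), lw=2)
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel("log10 normalized current")
        return ax
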
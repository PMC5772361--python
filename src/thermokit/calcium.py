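"""Calcium-imaging trace analysis: epoch dF/F, Morlet spectrograms, group tests.

The experimental design these tools serve alternates the bath between a low
and a high temperature setpoint while recording single-ROI GCaMP
fluorescence.  The summary statistic per cell is

    dF/F = (F_high - F_low) / F_low,

the relative change of mean fluorescence between the temperature epochs,
which is proportional to the change in overall firing activity.  Spectral
structure (oscillation bands in the ~1-4 Hz range) is examined with a
continuous wavelet transform using a complex Morlet mother wavelet
(center-frequency parameter omega0 = 6), and cell populations are compared
with an unpaired Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats

__all__ = [
    "FluorescenceTrace",
    "Epoch",
    "EpochStats",
    "Spectrogram",
    "GroupComparison",
    "epoch_segments",
    "delta_f_over_f",
    "morlet_cwt",
    "band_power_by_epoch",
    "compare_groups",
    "classify_tonic",
]

#: Morlet center-frequency parameter omega0=6 expressed as PyWavelets'
#: complex-Morlet (bandwidth B, center frequency C) pair: the classical
#: wavelet exp(i*omega0*t - t^2/2) is cmor with B=2 and C=omega0/(2*pi).
MORLET_OMEGA0 = 6.0
_CMOR_B = 2.0
_CMOR_C = MORLET_OMEGA0 / (2.0 * np.pi)


class AnalysisError(ValueError):
    pass


@dataclass
class FluorescenceTrace:
    """Single-ROI fluorescence with the bath-temperature channel."""

    time_s: np.ndarray
    fluorescence: np.ndarray  # arbitrary units, >= 0
    temperature_C: np.ndarray
    frame_interval_s: float
    roi_id: str = "roi0"
    genotype: str = "control"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        n = self.time_s.size
        if self.fluorescence.size != n or self.temperature_C.size != n:
            raise AnalysisError("all channels must share the time base")
        if np.any(self.fluorescence < 0):
            raise AnalysisError("fluorescence must be non-negative")
        if n > 2:
            dt = np.diff(self.time_s)
            if dt.min() <= 0:
                raise AnalysisError("time must be strictly increasing")
            if (dt.max() - dt.min()) > 0.01 * dt.mean():
                raise AnalysisError("sampling must be uniform within 1%")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s


@dataclass(frozen=True)
class Epoch:
    start_s: float
    end_s: float
    label: str  # "low" | "high"


@dataclass(frozen=True)
class EpochStats:
    """Mean fluorescence per temperature epoch and the dF/F ratio."""

    f_low: float
    f_high: float
    delta_f_over_f: float


@dataclass
class Spectrogram:
    """Time-frequency magnitude of a trace, with a cone-of-influence mask.

    ``magnitude[i, j]`` is the CWT magnitude at ``frequencies_hz[i]`` and
    ``times_s[j]``; ``coi[i, j]`` is True where the estimate is within one
    wavelet support of a trace edge and should be excluded from averages.
    """

    frequencies_hz: np.ndarray
    times_s: np.ndarray
    magnitude: np.ndarray
    coi: np.ndarray

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(self.times_s, self.frequencies_hz, self.magnitude, shading="auto")
        ax.set_yscale("log")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        return ax


def epoch_segments(
    time_s: np.ndarray,
    temperature_C: np.ndarray,
    t_low_C: float,
    t_high_C: float,
    guard_s: float = 10.0,
    tolerance_C: float = 1.0,
) -> list[Epoch]:
    """Plateau intervals at the two setpoints, trimmed by a guard margin.

    A plateau is a contiguous run with temperature within ``tolerance_C`` of
    a setpoint lasting at least ``2 * guard_s``; ``guard_s`` is cut from both
    ends so transition samples never contaminate epoch averages.
    """
    time_s = np.asarray(time_s, dtype=float)
    temperature_C = np.asarray(temperature_C, dtype=float)
    epochs: list[Epoch] = []
    for setpoint, label in ((t_low_C, "low"), (t_high_C, "high")):
        near = np.abs(temperature_C - setpoint) <= tolerance_C
        edges = np.flatnonzero(np.diff(near.astype(int)))
        starts = list(edges[near[edges + 1]] + 1) if edges.size else []
        ends = list(edges[~near[edges + 1]] + 1) if edges.size else []
        if near[0]:
            starts.insert(0, 0)
        if near[-1]:
            ends.append(near.size)
        for s, e in zip(starts, ends):
            t0, t1 = time_s[s], time_s[e - 1]
            if (t1 - t0) >= 2 * guard_s:
                epochs.append(Epoch(t0 + guard_s, t1 - guard_s, label))
    labels = {e.label for e in epochs}
    if "low" not in labels or "high" not in labels:
        observed = np.unique(np.round(temperature_C))
        raise AnalysisError(
            f"no qualifying plateau at both setpoints ({t_low_C}, {t_high_C}) C; "
            f"observed dwell temperatures: {observed.tolist()}"
        )
    return sorted(epochs, key=lambda e: e.start_s)


def _epoch_mask(time_s: np.ndarray, epochs: list[Epoch], label: str) -> np.ndarray:
    m = np.zeros(time_s.size, dtype=bool)
    for e in epochs:
        if e.label == label:
            m |= (time_s >= e.start_s) & (time_s <= e.end_s)
    return m


def delta_f_over_f(trace: FluorescenceTrace, epochs: list[Epoch]) -> EpochStats:
    """Epoch means and ``(F_high - F_low) / F_low`` over pooled epochs."""
    low = _epoch_mask(trace.time_s, epochs, "low")
    high = _epoch_mask(trace.time_s, epochs, "high")
    if not low.any() or not high.any():
        raise AnalysisError("both epoch classes must be non-empty")
    f_low = float(trace.fluorescence[low].mean())
    f_high = float(trace.fluorescence[high].mean())
    if f_low <= 0:
        raise AnalysisError("mean low-temperature fluorescence must be positive")
    return EpochStats(f_low, f_high, (f_high - f_low) / f_low)


def morlet_cwt(
    trace: FluorescenceTrace,
    f_min_hz: float = 0.25,
    f_max_hz: float = 8.0,
    n_freqs: int = 48,
) -> Spectrogram:
    """Continuous wavelet transform magnitude with a Morlet mother wavelet.

    Frequencies are log-spaced on [f_min, f_max]; f_max must stay below the
    Nyquist frequency and the trace must cover at least three cycles of
    f_min.  The signal mean is removed before the transform so a constant
    trace maps to zero magnitude.
    """
    dt = trace.frame_interval_s
    nyquist = 0.5 / dt
    if f_max_hz >= nyquist:
        raise AnalysisError(f"f_max {f_max_hz} Hz >= Nyquist {nyquist:.3g} Hz")
    duration = trace.time_s[-1] - trace.time_s[0]
    if duration < 3.0 / f_min_hz:
        raise AnalysisError("trace shorter than three cycles of f_min")

    freqs = np.logspace(np.log10(f_min_hz), np.log10(f_max_hz), n_freqs)
    wavelet = pywt.ContinuousWavelet(f"cmor{_CMOR_B}-{_CMOR_C}")
    scales = _CMOR_C / (freqs * dt)
    signal = trace.fluorescence - trace.fluorescence.mean()
    coefs, _ = pywt.cwt(signal, scales, wavelet, sampling_period=dt)
    magnitude = np.abs(coefs)

    # cone of influence: sqrt(2) * wavelet time spread (sigma_t = scale*dt
    # for B=2) from either edge
    n = signal.size
    coi = np.zeros((n_freqs, n), dtype=bool)
    idx = np.arange(n)
    for i, s in enumerate(scales):
        edge = int(np.ceil(np.sqrt(2.0) * s * np.sqrt(_CMOR_B / 2.0)))
        coi[i] = (idx < edge) | (idx >= n - edge)
    return Spectrogram(freqs, trace.time_s.copy(), magnitude, coi)


def band_power_by_epoch(
    spec: Spectrogram, band_hz: tuple[float, float], epochs: list[Epoch]
) -> dict[str, float]:
    """Mean spectrogram magnitude over a frequency band per epoch class.

    Cone-of-influence samples are excluded.  Raises if the band or the
    epochs do not intersect the spectrogram.
    """
    fm = (spec.frequencies_hz >= band_hz[0]) & (spec.frequencies_hz <= band_hz[1])
    if not fm.any():
        raise AnalysisError(f"band {band_hz} Hz outside the spectrogram range")
    out: dict[str, float] = {}
    for label in ("low", "high"):
        tm = _epoch_mask(spec.times_s, epochs, label)
        if not tm.any():
            continue
        cell = spec.magnitude[np.ix_(fm, tm)]
        keep = ~spec.coi[np.ix_(fm, tm)]
        if not keep.any():
            raise AnalysisError(f"band x {label}-epoch rectangle entirely inside the cone of influence")
        out[label] = float(cell[keep].mean())
    if not out:
        raise AnalysisError("no epoch intersects the spectrogram")
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-sided Welch t-test between two dF/F populations."""

    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def summary(self) -> str:
        return (
            "Welch unpaired t-test on dF/F\n"
            f"  group A: {self.mean_a:+.4f} +/- {self.sd_a:.4f} (n={self.n_a})\n"
            f"  group B: {self.mean_b:+.4f} +/- {self.sd_b:.4f} (n={self.n_b})\n"
            f"  t = {self.t_statistic:.3f}, p = {self.p_value:.3g}"
        )


def compare_groups(stats_a, stats_b) -> GroupComparison:
    """Two-sided unpaired Welch t-test between two lists of dF/F values."""
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs at least two observations")
    if a.size == b.size and np.array_equal(a, b):
        # degenerate identical groups: t = 0, p = 1 (scipy returns nan)
        return GroupComparison(
            0.0, 1.0, float(a.mean()), float(a.std(ddof=1)), a.size,
            float(b.mean()), float(b.std(ddof=1)), b.size,
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        float(t), float(p),
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
    )


def classify_tonic(
    trace: FluorescenceTrace,
    epochs: list[Epoch],
    events_per_s: float = 0.2,
    noise_k: float = 3.0,
    smooth_s: float = 0.2,
) -> bool:
    """Classify low-temperature activity as tonic vs quiescent.

    A cell is tonic if its rate of suprathreshold fluorescence events at the
    low setpoint is at least ``events_per_s``.  The event threshold is a
    baseline (10th percentile of the low-epoch trace) plus ``noise_k`` noise
    standard deviations, with the noise level estimated from the median
    absolute first difference; onsets are counted on a ``smooth_s`` boxcar
    average of the trace.  Anchoring the threshold to a low percentile
    rather than the median keeps it valid when events are dense enough to
    shift the median itself.  The rule (rate cut-off, percentile anchor,
    and robust noise scale) is a package convention, kept configurable.
    """
    low = _epoch_mask(trace.time_s, epochs, "low")
    if not low.any():
        raise AnalysisError("no low-temperature epoch")
    f = trace.fluorescence[low]
    # per-sample noise from first differences; robust to the slow event kernel
    sigma = 1.4826 * np.median(np.abs(np.diff(f))) / np.sqrt(2.0)
    width = max(1, int(round(smooth_s / trace.frame_interval_s)))
    kernel = np.ones(width) / width
    smoothed = np.convolve(f, kernel, mode="same")
    thresh = np.percentile(smoothed, 10.0) + noise_k * max(sigma, 1e-12)
    above = smoothed > thresh
    onsets = int(np.sum(np.diff(above.astype(int)) == 1)) + int(above[0])
    duration = low.sum() * trace.frame_interval_s
    return onsets / duration >= events_per_s
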
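"""Detection of seizure-like events (SLEs) in local field potential traces.

An accepted SLE must satisfy three electrographic criteria:

1. a negative deflection of the field potential of at least 0.5 mV relative
   to the local pre-event baseline,
2. persistence of the deflection for at least 10 s,
3. superimposed ripple-band discharges (band power elevated above the
   pre-event level).

Detection operates on a low-pass envelope of the (drift-corrected) trace;
onset and offset are placed at the 50 % crossings of the peak DC deflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "PhaseWindow",
    "LFPTrace",
    "SLEEvent",
    "PhaseSummary",
    "DetectionParams",
    "remove_drift",
    "detect_sles",
    "check_slice_inclusion",
    "summarize_phase",
]


@dataclass(frozen=True)
class PhaseWindow:
    """Labeled half-open time interval ``[start_s, end_s)`` of a protocol phase."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"phase {self.label!r}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def contains(self, t_s: float) -> bool:
        return self.start_s <= t_s < self.end_s


@dataclass
class LFPTrace:
    """Sampled extracellular voltage with protocol-phase annotations.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    phase_windows : sequence of PhaseWindow
        Ordered, non-overlapping intervals within the trace span.  May be
        empty, in which case detected events carry a null phase label.
    metadata : dict
        Free-form experiment metadata (slice/animal ids, group label,
        viability flag, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    phase_windows: tuple[PhaseWindow, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.phase_windows = tuple(self.phase_windows)
        prev_end = 0.0
        for w in self.phase_windows:
            if w.start_s < prev_end - 1e-9:
                raise ValueError("phase windows must be ordered and non-overlapping")
            if w.end_s > self.duration_s + 1e-6:
                raise ValueError(f"phase {w.label!r} extends beyond the trace")
            prev_end = w.end_s

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    def phase_of(self, t_s: float) -> str | None:
        for w in self.phase_windows:
            if w.contains(t_s):
                return w.label
        return None


@dataclass(frozen=True)
class SLEEvent:
    """One accepted seizure-like event."""

    onset_s: float
    offset_s: float
    duration_s: float
    dc_shift_amplitude_mV: float
    ripple_confirmed: bool = True
    phase_label: str | None = None


@dataclass(frozen=True)
class PhaseSummary:
    """Per-phase event statistics.

    ``sle_frequency_per_min`` counts every in-phase event over the full
    phase duration; duration/amplitude means are computed over the last
    ``n_events_analyzed`` (up to k, default 5) events of the phase so that
    drug effects have reached a plateau.
    """

    phase_label: str
    sle_frequency_per_min: float
    mean_duration_s: float
    mean_dc_shift_mV: float
    n_events_total: int
    n_events_analyzed: int


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings; thresholds default to the canonical 0.5 mV / 10 s."""

    dc_threshold_mv: float = 0.5
    min_duration_s: float = 10.0
    lowpass_hz: float = 1.0
    ripple_band: tuple[float, float] = (100.0, 200.0)
    ripple_factor: float = 3.0
    ripple_sustain_s: float = 1.0
    baseline_window_s: float = 10.0
    merge_gap_s: float = 5.0
    candidate_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.dc_threshold_mv <= 0:
            raise ValueError("dc_threshold_mv must be positive")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")
        lo, hi = self.ripple_band
        if not 0 < lo < hi:
            raise ValueError("ripple_band must satisfy 0 < low < high")


_ENV_RATE_HZ = 10.0  # resolution of the DC envelope / power grid (0.1 s)


def _decimate_mean(x: np.ndarray, dec: int) -> np.ndarray:
    n = len(x) // dec
    return x[: n * dec].reshape(n, dec).mean(axis=1)


def _dc_envelope(x: np.ndarray, fs: float, cutoff_hz: float, dec: int) -> np.ndarray:
    """Low-pass DC envelope on the decimated grid (block mean + Butterworth)."""
    env = _decimate_mean(x, dec)
    env_fs = fs / dec
    if cutoff_hz < 0.45 * env_fs and len(env) > 30:
        sos = signal.butter(4, cutoff_hz, btype="low", fs=env_fs, output="sos")
        env = signal.sosfiltfilt(sos, env)
    return env


def _ripple_power(
    x: np.ndarray, fs: float, band: tuple[float, float], dec: int
) -> np.ndarray:
    """Smoothed ripple-band power (1 s window) on the decimated grid."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        raise ValueError("ripple band incompatible with sampling rate")
    sos = signal.butter(4, (lo, hi), btype="band", fs=fs, output="sos")
    r = signal.sosfilt(sos, x)
    p = _decimate_mean(r * r, dec)
    win = max(1, int(round(fs / dec)))
    return ndimage.uniform_filter1d(p, size=win, mode="nearest")


def remove_drift(trace: LFPTrace, cutoff_hz: float = 0.005) -> LFPTrace:
    """Subtract minutes-scale baseline wander while preserving DC shifts.

    The drift estimate is a running median over a window of ``1 / cutoff_hz``
    seconds computed on a decimated copy of the trace.  Events lasting tens
    of seconds occupy well under half of that window, so their plateau
    amplitude survives to within a few percent.

    Raises
    ------
    ValueError
        On an empty trace or a cutoff at/above Nyquist.
    """
    if len(trace.samples) == 0:
        raise ValueError("cannot remove drift from an empty trace")
    if not 0 < cutoff_hz < trace.sampling_rate / 2:
        raise ValueError("cutoff_hz must lie in (0, Nyquist)")
    fs = trace.sampling_rate
    x = trace.samples
    window_s = 1.0 / cutoff_hz
    # decimate to ~4 Hz before the median filter; exact rate is immaterial
    step = max(1, int(round(fs / 4.0)))
    n_dec = len(x) // step
    if n_dec < 5:
        baseline = np.full_like(x, np.median(x))
    else:
        coarse = x[: n_dec * step].reshape(n_dec, step).mean(axis=1)
        size = int(round(window_s * fs / step))
        size = max(3, size | 1)  # odd
        med = ndimage.median_filter(coarse, size=size, mode="nearest")
        t_coarse = (np.arange(n_dec) + 0.5) * step / fs
        t = np.arange(len(x)) / fs
        baseline = np.interp(t, t_coarse, med)
    return replace(trace, samples=x - baseline)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as half-open index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _longest_true_run(mask: np.ndarray) -> int:
    best = 0
    for a, b in _runs(mask):
        best = max(best, b - a)
    return best


def detect_sles(
    trace: LFPTrace, params: DetectionParams | None = None
) -> list[SLEEvent]:
    """Detect SLEs satisfying the three electrographic criteria.

    The trace is expected to be drift-corrected (see :func:`remove_drift`).
    Returns maximal event intervals sorted by onset; each event is assigned
    the phase containing its onset (or ``None`` outside any phase).

    Raises
    ------
    ValueError
        If the trace contains non-finite samples.
    """
    if params is None:
        params = DetectionParams()
    x = trace.samples
    if len(x) == 0:
        return []
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    fs = trace.sampling_rate
    dec = max(1, int(round(fs / _ENV_RATE_HZ)))
    env_fs = fs / dec
    lp = _dc_envelope(x, fs, params.lowpass_hz, dec)
    power = _ripple_power(x, fs, params.ripple_band, dec)
    power = power[: len(lp)]

    thr = params.dc_threshold_mv
    b0 = float(np.median(lp))
    cand = lp < b0 - params.candidate_fraction * thr
    runs = _runs(cand)
    # merge candidate runs separated by brief returns toward baseline
    merged: list[tuple[int, int]] = []
    gap = int(params.merge_gap_s * env_fs)
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    bw = max(1, int(params.baseline_window_s * env_fs))
    sustain = max(1, int(params.ripple_sustain_s * env_fs))
    margin = int(60.0 * env_fs)
    events: list[SLEEvent] = []
    last_offset_idx = -1
    for a, b in merged:
        if a <= last_offset_idx:
            continue
        seg = lp[a:b]
        imin = a + int(np.argmin(seg))
        pre = lp[max(0, a - bw) : a]
        local_b = float(np.median(pre)) if len(pre) else b0
        depth = local_b - lp[imin]
        if depth < thr:
            continue
        half = local_b - 0.5 * depth
        # onset: last sample at/above the half level left of the peak
        lo = max(0, a - margin)
        left = np.nonzero(lp[lo:imin] >= half)[0]
        onset_idx = lo + left[-1] + 1 if len(left) else lo
        hi = min(len(lp), b + margin)
        right = np.nonzero(lp[imin:hi] >= half)[0]
        offset_idx = imin + right[0] - 1 if len(right) else hi - 1
        duration = (offset_idx - onset_idx) / env_fs
        if duration < params.min_duration_s:
            continue
        # criterion 3: ripple-band power sustained above pre-event level
        pb = float(np.median(power[max(0, onset_idx - bw) : onset_idx])) if onset_idx else float(np.median(power))
        pb = max(pb, 1e-12)
        above = power[onset_idx : offset_idx + 1] > params.ripple_factor * pb
        if _longest_true_run(above) < sustain:
            continue
        onset_s = onset_idx / env_fs
        events.append(
            SLEEvent(
                onset_s=onset_s,
                offset_s=offset_idx / env_fs,
                duration_s=duration,
                dc_shift_amplitude_mV=float(depth),
                ripple_confirmed=True,
                phase_label=trace.phase_of(onset_s),
            )
        )
        last_offset_idx = offset_idx
    events.sort(key=lambda e: e.onset_s)
    return events


def check_slice_inclusion(
    events: Sequence[SLEEvent],
    fourap_start_s: float = 0.0,
    limit_min: float = 45.0,
) -> bool:
    """True iff at least one event starts within ``limit_min`` of 4-AP onset."""
    limit = fourap_start_s + limit_min * 60.0
    return any(fourap_start_s <= e.onset_s <= limit for e in events)


def summarize_phase(
    events: Sequence[SLEEvent],
    phase_window: PhaseWindow,
    k: int = 5,
    trace_duration_s: float | None = None,
) -> PhaseSummary:
    """Summarize one protocol phase.

    Frequency counts all events whose onset falls in the phase, divided by
    the full phase duration in minutes.  Duration and DC-shift means use the
    last ``k`` (3-5) in-phase events, or all of them if fewer exist; with
    zero events the means are NaN.
    """
    if not 3 <= k <= 5:
        raise ValueError("k must be between 3 and 5")
    if trace_duration_s is not None and phase_window.end_s > trace_duration_s + 1e-6:
        raise ValueError("phase window extends beyond the trace")
    in_phase = sorted(
        (e for e in events if phase_window.contains(e.onset_s)),
        key=lambda e: e.onset_s,
    )
    n = len(in_phase)
    freq = n / phase_window.duration_min
    tail = in_phase[-k:]
    if tail:
        mean_dur = float(np.mean([e.duration_s for e in tail]))
        mean_amp = float(np.mean([e.dc_shift_amplitude_mV for e in tail]))
    else:
        mean_dur = float("nan")
        mean_amp = float("nan")
    return PhaseSummary(
        phase_label=phase_window.label,
        sle_frequency_per_min=freq,
        mean_duration_s=mean_dur,
        mean_dc_shift_mV=mean_amp,
        n_events_total=n,
        n_events_analyzed=len(tail),
    )
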
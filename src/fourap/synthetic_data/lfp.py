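"""Synthetic local field potential traces with known event ground truth.

Events are placed by a renewal process per protocol phase: successive
onsets are separated by the previous event's duration plus a refractory
gap of at least 30 s, with the remaining waiting time drawn from a gamma
distribution whose mean keeps the overall rate at the phase's nominal
value.  The gamma shape (default 4) reproduces the fairly regular spacing
seen in this preparation while keeping count statistics close to the
renewal expectation.

Each event waveform satisfies the three detection criteria by
construction: a negative DC plateau of the drawn amplitude (>= 0.5 mV), a
duration of tens of seconds (>= 10 s), and superimposed ripple-band
oscillations (continuous during the ~10 s tonic phase, 1 Hz bursts of
after-discharges during the clonic remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .. import PHASES
from ..lfp_events import LFPTrace, PhaseWindow
from .specs import GroupSpec

__all__ = [
    "GroundTruthEvent",
    "GroundTruth",
    "generate_lfp",
    "render_event_waveform",
]

DEFAULT_SAMPLING_RATE = 5000.0
MIN_EVENT_DURATION_S = 15.0
MIN_EVENT_AMPLITUDE_MV = 0.65
REFRACTORY_S = 30.0
END_MARGIN_S = 15.0
BOUNDARY_STANDOFF_S = 5.0
TONIC_S = 10.0


@dataclass
class GroundTruthEvent:
    """One generated event; optical involvement is filled in lazily."""

    onset_s: float
    duration_s: float
    amplitude_mv: float
    onset_region: str
    phase_label: str
    ripple_hz: float = 150.0
    involvement: dict[str, np.ndarray] | None = None

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class GroundTruth:
    """Generated events for one trace, ordered and non-overlapping."""

    events: list[GroundTruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for e in self.events:
            if e.onset_s < prev_end:
                raise ValueError("ground-truth events overlap")
            prev_end = e.offset_s

    def in_phase(self, phase_label: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.phase_label == phase_label]

    def __len__(self) -> int:
        return len(self.events)


def _truncated_normal(rng, mean: float, sd: float, lower: float) -> float:
    for _ in range(64):
        v = rng.normal(mean, sd)
        if v >= lower:
            return float(v)
    return float(lower)


def render_event_waveform(
    duration_s: float,
    amplitude_mv: float,
    sampling_rate: float,
    rng: np.random.Generator | None = None,
    ripple_hz: float = 150.0,
    ripple_amplitude_mv: float = 0.15,
    rise_s: float = 1.0,
    fall_s: float = 2.0,
) -> np.ndarray:
    """Voltage waveform of a single event, starting at its onset.

    Morphology: a fast onset transient, a negative DC plateau held near the
    drawn amplitude (rise/fall at the edges so the 50 %-crossing duration
    matches ``duration_s``), continuous ripple during the tonic phase and
    ripple bursts (after-discharges) during the clonic phase.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fs = sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    envelope = np.ones(n)
    n_rise = max(1, int(rise_s * fs))
    n_fall = max(1, int(fall_s * fs))
    envelope[:n_rise] = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise))
    envelope[n - n_fall :] = 0.5 * (
        1 + np.cos(np.pi * np.arange(n_fall) / n_fall)
    )
    # mild clonic modulation of the plateau; stays >= 0.9 so the half-peak
    # crossings remain at the waveform edges
    clonic = t > TONIC_S
    envelope[clonic] *= 1.0 - 0.05 * (1 + np.sin(2 * np.pi * 0.5 * t[clonic]))

    x = -amplitude_mv * envelope

    # sharp onset transient (fast, does not bias the low-pass DC estimate)
    n_tr = max(1, int(0.3 * fs))
    x[:n_tr] += -0.25 * np.exp(-np.arange(n_tr) / (0.06 * fs)) * np.sin(
        2 * np.pi * 20.0 * t[:n_tr]
    )

    # ripple-band oscillation: continuous while tonic, bursty while clonic
    burst_env = np.ones(n)
    frac = np.mod(t, 1.0)
    burst_env[clonic] = (frac[clonic] < 0.4).astype(float)
    phase0 = rng.uniform(0, 2 * np.pi)
    ripple = ripple_amplitude_mv * np.sin(2 * np.pi * ripple_hz * t + phase0)
    x += ripple * burst_env * np.clip(envelope / 0.9, 0.0, 1.0)
    return x


def _upsample_hold(values: np.ndarray, n: int) -> np.ndarray:
    """Zero-order-hold upsampling of a coarse series to ``n`` samples."""
    factor = int(np.ceil(n / len(values)))
    return np.repeat(values, factor)[:n]


def _background_noise(rng, n: int, fs: float, noise_sd_mv: float) -> np.ndarray:
    """White noise plus a low-frequency (pink-ish) component.

    The slow component only has content below ~2 Hz, so it is synthesized
    on a 20 Hz grid and interpolated up, which keeps long traces cheap.
    """
    white = rng.standard_normal(n) * noise_sd_mv
    slow_fs = min(20.0, fs)
    n_slow = max(8, int(n * slow_fs / fs))
    slow = rng.standard_normal(n_slow)
    sos = signal.butter(2, min(2.0, 0.4 * slow_fs), btype="low", fs=slow_fs, output="sos")
    slow = signal.sosfilt(sos, slow)
    sd = slow.std() or 1.0
    slow *= 0.5 * noise_sd_mv / sd
    white += _upsample_hold(slow, n)
    return white


def _sample_phase_events(
    rng,
    window: PhaseWindow,
    rate_per_min: float,
    spec: GroupSpec,
    prev_end: float,
    gap_shape: float,
    recording_end_s: float,
) -> tuple[list[GroundTruthEvent], float]:
    events: list[GroundTruthEvent] = []
    if rate_per_min <= 0:
        return events, prev_end
    pi = spec.phase_index(window.label)
    mean_interval = 60.0 / rate_per_min
    regions = list(spec.onset_region_weights)
    weights = np.array([spec.onset_region_weights[r] for r in regions], dtype=float)
    weights = weights / weights.sum()
    # equilibrium-like start: first onset uniform within one mean interval
    t = max(window.start_s + rng.uniform(0.0, mean_interval), prev_end + REFRACTORY_S)
    # detected onsets sit ~0.5 s after the true onset (50 %-crossing
    # placement), so keep events clear of the phase boundary to make the
    # phase attribution of every event unambiguous
    while t < window.end_s - BOUNDARY_STANDOFF_S:
        duration = _truncated_normal(
            rng, spec.duration_mean_s[pi], spec.duration_sd_s, MIN_EVENT_DURATION_S
        )
        # the last event must return to baseline before the recording ends,
        # otherwise its DC shift is not measurable
        if t + duration > recording_end_s - END_MARGIN_S:
            break
        amplitude = _truncated_normal(
            rng,
            spec.dc_amplitude_mean_mv[pi],
            spec.dc_amplitude_sd_mv,
            MIN_EVENT_AMPLITUDE_MV,
        )
        region = regions[rng.choice(len(regions), p=weights)]
        events.append(
            GroundTruthEvent(
                onset_s=float(t),
                duration_s=duration,
                amplitude_mv=amplitude,
                onset_region=region,
                phase_label=window.label,
                ripple_hz=float(rng.uniform(120.0, 180.0)),
            )
        )
        prev_end = t + duration
        free = max(mean_interval - REFRACTORY_S - duration, 1.0)
        gap = duration + REFRACTORY_S + rng.gamma(gap_shape, free / gap_shape)
        t = t + gap
    return events, prev_end


def generate_lfp(
    spec: GroupSpec,
    seed: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    phases: Sequence[str] = PHASES,
    noise_sd_mv: float = 0.04,
    drift_amplitude_mv: float = 0.2,
    drift_period_min: float = 25.0,
    gap_shape: float = 4.0,
    tail_s: float = 90.0,
    metadata: dict | None = None,
) -> tuple[LFPTrace, GroundTruth]:
    """Simulate one slice recording for the requested protocol phases.

    The recording extends ``tail_s`` seconds beyond the last phase so that
    an event starting near the end of a phase can complete and be measured,
    as it would be in a real experiment.  Returns the trace (with phase
    annotations and metadata) and the exact event ground truth.
    Deterministic for a fixed seed.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    phases = tuple(phases)
    for p in phases:
        if p not in PHASES:
            raise ValueError(f"unknown phase {p!r}")
    windows = []
    t0 = 0.0
    for label in PHASES:
        if label not in phases:
            continue
        dur_s = spec.phase_durations_min[spec.phase_index(label)] * 60.0
        if dur_s <= 0:
            raise ValueError("phase durations must be positive")
        windows.append(PhaseWindow(label, t0, t0 + dur_s))
        t0 += dur_s

    rng = np.random.default_rng(seed)
    fs = sampling_rate
    recording_s = t0 + max(tail_s, 0.0)
    n = int(round(recording_s * fs))
    x = _background_noise(rng, n, fs, noise_sd_mv)

    if drift_amplitude_mv and n:
        # sinusoidal wander plus a linear ramp, rendered on a coarse grid
        n_coarse = max(8, int(recording_s))  # ~1 Hz
        tc = np.linspace(0.0, recording_s, n_coarse)
        f_drift = 1.0 / (drift_period_min * 60.0)
        drift = drift_amplitude_mv * np.sin(
            2 * np.pi * f_drift * tc + rng.uniform(0, 2 * np.pi)
        )
        drift += rng.uniform(-1, 1) * drift_amplitude_mv * tc / recording_s
        x += _upsample_hold(drift, n)

    rates = spec.event_rate_per_phase
    all_events: list[GroundTruthEvent] = []
    prev_end = -np.inf
    for w in windows:
        events, prev_end = _sample_phase_events(
            rng,
            w,
            rates[w.label],
            spec,
            prev_end,
            gap_shape,
            recording_end_s=recording_s,
        )
        all_events.extend(events)

    for e in all_events:
        i0 = int(round(e.onset_s * fs))
        wave = render_event_waveform(
            e.duration_s, e.amplitude_mv, fs, rng=rng, ripple_hz=e.ripple_hz
        )
        i1 = min(n, i0 + len(wave))
        x[i0:i1] += wave[: i1 - i0]

    meta = {"group_label": spec.group_label, "seed": int(seed), "viable": True}
    if metadata:
        meta.update(metadata)
    trace = LFPTrace(
        samples=x, sampling_rate=fs, phase_windows=tuple(windows), metadata=meta
    )
    return trace, GroundTruth(events=all_events)
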
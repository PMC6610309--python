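"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the production code paths: the event oracle uses a
boxcar envelope, explicit Python run-scanning and FFT periodogram band
power; the involvement oracle is a triple loop over pixels, frames and
consecutive runs.
"""

from __future__ import annotations

import numpy as np


def detect_events_oracle(
    samples: np.ndarray,
    fs: float,
    dc_threshold_mv: float = 0.5,
    min_duration_s: float = 10.0,
    ripple_band: tuple[float, float] = (100.0, 200.0),
    ripple_factor: float = 3.0,
) -> list[tuple[float, float]]:
    """Exhaustive three-criteria evaluation; returns (onset_s, offset_s) pairs."""
    n1s = max(1, int(fs))
    kernel = np.ones(n1s) / n1s
    env = np.convolve(samples, kernel, mode="same")
    step = max(1, int(fs / 10))
    env10 = env[::step]
    fs10 = fs / step
    base = float(np.median(env10))

    cand = env10 < base - 0.5 * dc_threshold_mv
    runs: list[list[int]] = []
    i = 0
    while i < len(cand):
        if cand[i]:
            j = i
            while j < len(cand) and cand[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < 5 * fs10:
            merged[-1][1] = r[1]
        else:
            merged.append(r)

    def band_power(seg: np.ndarray) -> float:
        freqs = np.fft.rfftfreq(len(seg), 1.0 / fs)
        p = np.abs(np.fft.rfft(seg - seg.mean())) ** 2
        sel = (freqs >= ripple_band[0]) & (freqs <= ripple_band[1])
        return float(p[sel].sum() / len(seg))

    events = []
    for a, b in merged:
        pre = env10[max(0, a - int(10 * fs10)) : a]
        local = float(np.median(pre)) if len(pre) else base
        depth = local - env10[a:b].min()
        if depth < dc_threshold_mv:
            continue
        half = local - 0.5 * depth
        i0 = a
        while i0 > 0 and env10[i0 - 1] < half:
            i0 -= 1
        i1 = b - 1
        while i1 < len(env10) - 1 and env10[i1 + 1] < half:
            i1 += 1
        duration = (i1 - i0) / fs10
        if duration < min_duration_s:
            continue
        on = int(i0 / fs10 * fs)
        off = int(i1 / fs10 * fs)
        pre_powers = [
            band_power(samples[k : k + n1s])
            for k in range(max(0, on - 10 * n1s), max(0, on - n1s) + 1, n1s)
            if k + n1s <= len(samples)
        ]
        baseline_p = np.median(pre_powers) if pre_powers else band_power(samples[:n1s])
        event_powers = [
            band_power(samples[k : k + n1s])
            for k in range(on, off - n1s + 1, n1s)
            if k + n1s <= len(samples)
        ]
        if not any(p > ripple_factor * max(baseline_p, 1e-12) for p in event_powers):
            continue
        events.append((i0 / fs10, i1 / fs10))
    return events


def involvement_oracle(
    values: np.ndarray, threshold_pct: float, persistence_frames: int
) -> np.ndarray:
    """Per-pixel loop over all consecutive runs; returns the involvement map."""
    n_frames, height, width = values.shape
    out = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            run = 0
            for f in range(n_frames):
                v = values[f, r, c]
                if np.isfinite(v) and v >= threshold_pct:
                    run += 1
                    if run >= persistence_frames:
                        out[r, c] = True
                        break
                else:
                    run = 0
    return out
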
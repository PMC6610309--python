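import numpy as np
import pytest

from fourap.lfp_events import LFPTrace, PhaseWindow
from fourap.synthetic_data import build_region_masks, default_group_specs
from fourap.synthetic_data.lfp import render_event_waveform


@pytest.fixture(scope="session")
def masks():
    return build_region_masks()


@pytest.fixture(scope="session")
def specs():
    return default_group_specs()


@pytest.fixture(scope="session")
def control_spec(specs):
    return specs["control"]


@pytest.fixture(scope="session")
def lac33_spec(specs):
    return specs["LAC_33"]


def make_event_trace(
    onsets,
    durations,
    amplitudes,
    fs=500.0,
    total_s=300.0,
    noise_sd=0.02,
    seed=0,
    phase_windows=(),
    offset_mv=0.0,
):
    """Short trace with hand-placed events on a light noise floor."""
    rng = np.random.default_rng(seed)
    n = int(total_s * fs)
    x = rng.normal(0.0, noise_sd, n) + offset_mv
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        wave = render_event_waveform(dur, amp, fs, rng=rng)
        i0 = int(onset * fs)
        i1 = min(n, i0 + len(wave))
        x[i0:i1] += wave[: i1 - i0]
    return LFPTrace(
        samples=x,
        sampling_rate=fs,
        phase_windows=tuple(
            PhaseWindow(*w) if not isinstance(w, PhaseWindow) else w
            for w in phase_windows
        ),
    )
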
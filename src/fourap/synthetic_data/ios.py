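"""Synthetic 8-bit optical stacks for single events, with exact involvement.

For every region the generator selects the spec's target fraction of mask
pixels as *involved*; those pixels receive a transmittance transient whose
peak comfortably exceeds the 1 % involvement threshold and persists for the
whole event (far more than 10 frames).  The remaining mask pixels receive a
small sub-threshold transient.  Within the analysis ROI (a 20x20 square at
the region centroid, mirroring the measurement side) the local involved
fraction is tuned so that the ROI-mean peak equals the spec's regional
dT/T amplitude -- reproducing the situation where a region's mean optical
intensity falls because fewer ROI pixels reach threshold.

Frames carry Gaussian sensor noise (default sd 0.2 intensity units) which
also dithers the 8-bit quantization; per-ROI dT/T fluctuations stay below
0.1 %.  With ``noise_sd=0`` generation is noiseless and the ground-truth
involved sets satisfy the threshold/persistence rule exactly.
"""

from __future__ import annotations

import numpy as np

from ..ios_analysis import IOSSeries, place_roi
from .lfp import GroundTruthEvent
from .masks import RegionMaskSet
from .specs import GroupSpec

__all__ = ["generate_ios_series"]

INVOLVED_MIN_PCT = 1.8  # involved-pixel plateau, safely above the 1 % rule
SUBTHRESHOLD_PCT = 0.2  # non-involved mask pixels stay well below 1 %
TISSUE_BASE = 180
BACKGROUND_BASE = 60


def _expected_noise_peak_pct(
    noise_sd: float, roi_area: int, n_post_frames: int
) -> float:
    """Expected maximum of the ROI-mean noise over the post-onset frames.

    The measured ROI summary is the peak of the time course, so frame noise
    adds a small positive selection bias; the generator subtracts this
    expectation from the plateau target.  Gumbel approximation for the max
    of iid normals.
    """
    if noise_sd <= 0 or n_post_frames < 3:
        return 0.0
    sigma_pix = np.sqrt(1.0 / 12.0 + noise_sd**2)  # uniform dither + sensor
    sigma_roi = 100.0 * sigma_pix / (TISSUE_BASE * np.sqrt(roi_area))
    ln_f = np.log(n_post_frames)
    a = np.sqrt(2 * ln_f)
    return float(sigma_roi * (a - (np.log(ln_f) + np.log(4 * np.pi)) / (2 * a)))


def _involvement_layout(
    rng: np.random.Generator,
    mask: np.ndarray,
    roi_box: tuple[int, int, int, int],
    target_area_fraction: float,
    target_roi_peak_pct: float,
) -> tuple[np.ndarray, float, float]:
    """Choose involved pixels and amplitudes for one region.

    Returns (involved mask, involved amplitude %, sub-threshold amplitude %).
    """
    n_total = int(mask.sum())
    involved = np.zeros_like(mask)
    m = float(target_roi_peak_pct)
    f = float(np.clip(target_area_fraction, 0.0, 1.0))
    if f <= 0.0 and m <= 0.0:
        return involved, 0.0, 0.0

    a_inv = max(INVOLVED_MIN_PCT, m + 0.6)
    a_sub = min(SUBTHRESHOLD_PCT, 0.5 * m) if m > 0 else 0.0

    r0, c0, hh, ww = roi_box
    roi = np.zeros_like(mask)
    roi[r0 : r0 + hh, c0 : c0 + ww] = True
    roi &= mask
    n_roi = int(roi.sum())
    n_out_total = n_total - n_roi

    n_involved = int(round(f * n_total))
    if f > 0.0:
        f_roi = float(np.clip((m - a_sub) / (a_inv - a_sub), 0.0, 1.0))
        n_roi_inv = int(round(f_roi * n_roi))
    else:
        n_roi_inv = 0
    n_out_inv = int(np.clip(n_involved - n_roi_inv, 0, n_out_total))
    # keep the whole-region count exact even if the outside pool saturates
    n_roi_inv = int(np.clip(n_involved - n_out_inv, 0, n_roi))

    roi_idx = np.flatnonzero(roi.ravel())
    out_idx = np.flatnonzero((mask & ~roi).ravel())
    flat = involved.ravel()
    if n_roi_inv:
        flat[rng.choice(roi_idx, size=n_roi_inv, replace=False)] = True
    if n_out_inv:
        flat[rng.choice(out_idx, size=n_out_inv, replace=False)] = True
    return involved, a_inv, a_sub


def _pixel_profile(
    n_frames: int,
    onset_frame: int,
    latency_frames: int,
    plateau_frames: int,
    rise_frames: int = 2,
    fall_frames: int = 2,
) -> np.ndarray:
    """Unit-amplitude temporal profile (0..1) for one pixel group."""
    prof = np.zeros(n_frames)
    start = onset_frame + latency_frames
    for k in range(rise_frames):
        i = start + k
        if 0 <= i < n_frames:
            prof[i] = (k + 1) / (rise_frames + 1)
    p0 = start + rise_frames
    p1 = min(p0 + plateau_frames, n_frames)
    prof[max(p0, 0) : p1] = 1.0
    for k in range(fall_frames):
        i = p1 + k
        if 0 <= i < n_frames:
            prof[i] = 1.0 - (k + 1) / (fall_frames + 1)
    return prof


def generate_ios_series(
    event: GroundTruthEvent,
    masks: RegionMaskSet,
    spec: GroupSpec,
    seed: int,
    frame_rate_hz: float = 2.0,
    n_control_frames: int = 20,
    noise_sd: float = 0.2,
    roi_size: int = 20,
    max_capture_s: float = 180.0,
    post_s: float = 10.0,
) -> tuple[IOSSeries, dict[str, np.ndarray]]:
    """Render one trigger-aligned stack for ``event``.

    Returns the 8-bit series plus the exact per-region involved-pixel
    ground truth.  The designated onset region rises first; all other
    regions follow with a latency of at least two frames.

    Raises
    ------
    ValueError
        If the captured event is too short to satisfy the control-window
        plus persistence requirements.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    pi = spec.phase_index(event.phase_label)
    duration_s = min(event.duration_s, max_capture_s)
    event_frames = int(np.ceil(duration_s * frame_rate_hz))
    # latency (<=4) + rise (2) + fall (2) frames must still leave a plateau
    # of >= 10 frames so involved pixels satisfy the persistence rule
    if event_frames < 18:
        raise ValueError(
            "captured event shorter than the involvement persistence window"
        )
    n_frames = n_control_frames + event_frames + int(np.ceil(post_s * frame_rate_hz))
    frame_times = (np.arange(n_frames) - n_control_frames + 0.5) / frame_rate_hz

    shape = masks.shape
    base = np.full(shape, float(BACKGROUND_BASE))
    for mask in masks.masks.values():
        base[mask] = TISSUE_BASE
    base += rng.integers(-6, 7, size=shape)  # static spatial texture

    dtt_true = np.zeros((n_frames,) + shape, dtype=np.float32)
    truth: dict[str, np.ndarray] = {}
    for region, mask in masks.masks.items():
        m_pct = spec.ios_peak_dtt_pct[region][pi]
        f_frac = spec.area_fraction_pct[region][pi] / 100.0
        roi_box = place_roi(mask, roi_size)
        if m_pct > 0:
            m_pct = max(
                0.0,
                m_pct
                - _expected_noise_peak_pct(
                    noise_sd, roi_box[2] * roi_box[3], n_frames - n_control_frames
                ),
            )
        involved, a_inv, a_sub = _involvement_layout(
            rng, mask, roi_box, f_frac, m_pct
        )
        truth[region] = involved
        if a_inv <= 0 and a_sub <= 0:
            continue
        latency = 0 if region == event.onset_region else int(2 + rng.integers(0, 3))
        prof = _pixel_profile(
            n_frames,
            onset_frame=n_control_frames,
            latency_frames=latency,
            plateau_frames=event_frames - latency - 4,
        )
        sub_mask = mask & ~involved
        dtt_true[:, involved] += np.float32(a_inv) * prof[:, None].astype(np.float32)
        if a_sub > 0:
            dtt_true[:, sub_mask] += np.float32(a_sub) * prof[:, None].astype(
                np.float32
            )

    intensity = base.astype(np.float32)[None, :, :] * (1.0 + dtt_true / np.float32(100.0))
    if noise_sd > 0:
        # width-1 uniform dither makes 8-bit rounding exactly unbiased;
        # the Gaussian term models sensor noise on top
        intensity += rng.random(intensity.shape, dtype=np.float32) - np.float32(0.5)
        intensity += rng.standard_normal(intensity.shape, dtype=np.float32) * np.float32(
            noise_sd
        )
    frames = np.clip(np.rint(intensity, out=intensity), 0, 255).astype(np.uint8)

    series = IOSSeries(
        frames=frames,
        frame_times_s=frame_times,
        n_control_frames=n_control_frames,
        masks=masks,
        event=event,
    )
    event.involvement = truth
    return series, truth
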
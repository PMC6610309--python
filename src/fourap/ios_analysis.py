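"""Intrinsic optical signal (IOS) quantification for trigger-aligned stacks.

The transmittance change of every pixel is expressed relative to a control
image (mean of the first 20 frames, captured before the electrical event
onset): ``dT/T[f, p] = 100 * (I[f, p] - C[p]) / C[p]``.

A pixel counts as *involved* in an event when its dT/T reaches the
threshold (default 1 %) in at least ``persistence_frames`` (default 10,
i.e. more than 9) consecutive frames.  The event area of an anatomical
region is the involved fraction of that region's mask, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "IOSSeries",
    "DTTStack",
    "RoiSummary",
    "InvolvementResult",
    "compute_dtt",
    "place_roi",
    "roi_intensity",
    "involvement_map",
    "sle_area",
    "onset_region",
    "render_pseudocolor",
]


def _as_mask_dict(masks) -> dict[str, np.ndarray]:
    """Accept a plain mapping or any object exposing ``.masks``."""
    if hasattr(masks, "masks"):
        masks = masks.masks
    return {str(k): np.asarray(v, dtype=bool) for k, v in masks.items()}


@dataclass
class IOSSeries:
    """Trigger-aligned 8-bit frame stack around one seizure-like event.

    ``frame_times_s`` are relative to the electrical event onset (negative
    before onset); the first ``n_control_frames`` frames must precede onset.
    """

    frames: np.ndarray
    frame_times_s: np.ndarray
    n_control_frames: int = 20
    masks: Mapping[str, np.ndarray] | None = None
    event: object | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (frame, row, col) stack")
        if len(self.frame_times_s) != len(self.frames):
            raise ValueError("frame_times_s length must match frame count")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if len(self.frames) < self.n_control_frames:
            raise ValueError("stack shorter than the control window")
        if np.any(self.frame_times_s[: self.n_control_frames] >= 0):
            raise ValueError("control frames must precede the event onset")


@dataclass
class DTTStack:
    """Per-frame, per-pixel dT/T values in percent of control intensity."""

    values: np.ndarray  # (frame, row, col) float32, NaN where invalid
    frame_times_s: np.ndarray
    n_control_frames: int


@dataclass(frozen=True)
class RoiSummary:
    """Square-ROI dT/T time course and its post-onset peak for one region."""

    region: str
    timecourse_pct: np.ndarray
    peak_pct: float
    roi_box: tuple[int, int, int, int]  # (row0, col0, height, width)


@dataclass
class InvolvementResult:
    involvement: np.ndarray  # boolean (row, col)
    area_pct: dict[str, float] = field(default_factory=dict)
    roi_dtt_pct: dict[str, float] = field(default_factory=dict)
    onset_region: str | None = None


def compute_dtt(series: IOSSeries) -> DTTStack:
    """Normalize a stack to dT/T (percent) against its control image.

    The control image is the mean of the first ``n_control_frames`` frames.
    Pixels with non-positive control intensity, and saturated pixels
    (control at the 8-bit ceiling), are marked NaN and excluded from all
    downstream means.
    """
    frames = series.frames.astype(np.float32)
    n = series.n_control_frames
    control = frames[:n].mean(axis=0, dtype=np.float32)
    invalid = control <= 0
    if series.frames.dtype == np.uint8:
        invalid |= control >= 254.5  # saturated
    safe = np.where(invalid, np.float32(1.0), control)
    values = np.float32(100.0) * (frames - control) / safe
    values[:, invalid] = np.nan
    return DTTStack(
        values=values,
        frame_times_s=series.frame_times_s,
        n_control_frames=n,
    )


def place_roi(
    mask: np.ndarray, roi_size: int = 20
) -> tuple[int, int, int, int]:
    """Place a square ROI inside ``mask``, nearest to the mask centroid.

    Among all positions where the ROI lies entirely inside the mask the one
    closest to the centroid is chosen.  If no such position exists the ROI
    is shrunk (with a warning) until one does.

    Returns ``(row0, col0, height, width)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    h, w = mask.shape
    size = min(roi_size, h, w)
    integral = np.pad(np.cumsum(np.cumsum(mask, axis=0), axis=1), ((1, 0), (1, 0)))
    while size >= 1:
        cov = (
            integral[size:, size:]
            - integral[:-size, size:]
            - integral[size:, :-size]
            + integral[:-size, :-size]
        )
        full = np.nonzero(cov == size * size)
        if len(full[0]):
            centers_r = full[0] + (size - 1) / 2.0
            centers_c = full[1] + (size - 1) / 2.0
            k = int(np.argmin((centers_r - cr) ** 2 + (centers_c - cc) ** 2))
            if size < roi_size:
                warnings.warn(
                    f"region mask cannot contain a {roi_size}x{roi_size} ROI; "
                    f"shrunk to {size}x{size}",
                    stacklevel=2,
                )
            return int(full[0][k]), int(full[1][k]), size, size
        size -= 1
    raise ValueError("region mask has no interior pixel")  # pragma: no cover


def roi_intensity(
    dtt: DTTStack,
    masks,
    roi_size: int = 20,
) -> dict[str, RoiSummary]:
    """Square-ROI mean dT/T time course per region and its post-onset peak."""
    out: dict[str, RoiSummary] = {}
    n = dtt.n_control_frames
    for region, mask in _as_mask_dict(masks).items():
        r0, c0, hh, ww = place_roi(mask, roi_size)
        block = dtt.values[:, r0 : r0 + hh, c0 : c0 + ww]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            tc = np.nanmean(block.reshape(len(block), -1), axis=1)
        post = tc[n:]
        peak = float(np.nanmax(post)) if len(post) else float("nan")
        out[region] = RoiSummary(
            region=region, timecourse_pct=tc, peak_pct=peak, roi_box=(r0, c0, hh, ww)
        )
    return out


def involvement_map(
    dtt: DTTStack,
    threshold_pct: float = 1.0,
    persistence_frames: int = 10,
) -> np.ndarray:
    """Boolean per-pixel involvement map.

    A pixel is involved iff its dT/T is at or above ``threshold_pct`` in at
    least ``persistence_frames`` *consecutive* frames anywhere in the
    captured series.  Pure thresholding; no spatial smoothing.
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    n_frames = len(dtt.values)
    if persistence_frames > n_frames:
        warnings.warn(
            "persistence exceeds stack length; no pixel can be involved",
            stacklevel=2,
        )
        return np.zeros(dtt.values.shape[1:], dtype=bool)
    above = dtt.values >= threshold_pct  # NaN compares False
    # sliding-window sum along the frame axis via a cumulative count
    csum = np.zeros((n_frames + 1,) + above.shape[1:], dtype=np.int32)
    np.cumsum(above, axis=0, out=csum[1:])
    window = csum[persistence_frames:] - csum[: n_frames - persistence_frames + 1]
    return (window == persistence_frames).any(axis=0)


def sle_area(involvement: np.ndarray, masks) -> dict[str, float]:
    """Involved percentage of each region's mask."""
    involvement = np.asarray(involvement, dtype=bool)
    out = {}
    for region, mask in _as_mask_dict(masks).items():
        total = int(mask.sum())
        if total == 0:
            raise ValueError(f"region {region!r} has an empty mask")
        out[region] = 100.0 * int((involvement & mask).sum()) / total
    return out


def onset_region(
    dtt: DTTStack,
    masks,
    onset_threshold_pct: float = 0.4,
    roi_size: int = 20,
) -> str | None:
    """Region whose ROI time course first crosses the onset threshold.

    Ties on the crossing frame are broken by the larger dT/T at that frame,
    then by the mask iteration order.  Returns ``None`` when no region
    crosses the threshold.
    """
    summaries = roi_intensity(dtt, masks, roi_size=roi_size)
    best: tuple[int, float, int] | None = None  # (frame, -dtt, order)
    best_region = None
    for order, (region, s) in enumerate(summaries.items()):
        crossing = np.nonzero(
            np.nan_to_num(s.timecourse_pct, nan=-np.inf) >= onset_threshold_pct
        )[0]
        if not len(crossing):
            continue
        f = int(crossing[0])
        key = (f, -float(s.timecourse_pct[f]), order)
        if best is None or key < best:
            best = key
            best_region = region
    return best_region


def render_pseudocolor(
    dtt: DTTStack,
    out_path,
    vmin: float = -1.0,
    vmax: float = 4.0,
    cmap: str = "jet",
    fps: float = 5.0,
):
    """Write the dT/T stack as a pseudo-color animation (GIF) or TIFF stack.

    Output is deterministic for a fixed input.  The container is chosen by
    file suffix: ``.gif`` (default) or ``.tif``/``.tiff`` (RGB multipage).
    """
    import matplotlib

    from pathlib import Path

    out_path = Path(out_path)
    norm = np.clip((dtt.values - vmin) / (vmax - vmin), 0.0, 1.0)
    norm = np.nan_to_num(norm, nan=0.0)
    colormap = matplotlib.colormaps[cmap]
    rgb = (colormap(norm)[..., :3] * 255).astype(np.uint8)
    suffix = out_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(out_path, rgb, photometric="rgb")
    else:
        import imageio.v3 as iio

        iio.imwrite(out_path, rgb, extension=".gif", duration=int(1000 / fps), loop=0)
    return out_path
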
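"""File formats: traces (HDF5/CSV), stacks (TIFF), masks (TIFF/JSON), tables.

All writers produce deterministic bytes for identical inputs (no
timestamps are embedded).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ios_analysis import IOSSeries
from .lfp_events import LFPTrace, PhaseWindow, SLEEvent

__all__ = [
    "write_trace_h5",
    "read_trace_h5",
    "write_trace_csv",
    "read_trace_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_masks_json",
    "read_masks_json",
    "write_masks_tiff",
    "write_events_csv",
    "read_events_csv",
    "write_events_json",
    "write_ground_truth_json",
]


def write_trace_h5(trace: LFPTrace, path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage_mV", data=trace.samples, compression="gzip")
        ds.attrs["sampling_rate_hz"] = trace.sampling_rate
        ds.attrs["phase_labels"] = [w.label for w in trace.phase_windows]
        ds.attrs["phase_starts_s"] = [w.start_s for w in trace.phase_windows]
        ds.attrs["phase_ends_s"] = [w.end_s for w in trace.phase_windows]
        ds.attrs["metadata_json"] = json.dumps(trace.metadata, sort_keys=True)
    return path


def read_trace_h5(path) -> LFPTrace:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["voltage_mV"]
        samples = ds[:]
        fs = float(ds.attrs["sampling_rate_hz"])
        labels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in ds.attrs.get("phase_labels", [])
        ]
        starts = list(ds.attrs.get("phase_starts_s", []))
        ends = list(ds.attrs.get("phase_ends_s", []))
        meta = json.loads(ds.attrs.get("metadata_json", "{}"))
    windows = tuple(
        PhaseWindow(l, float(a), float(b)) for l, a, b in zip(labels, starts, ends)
    )
    return LFPTrace(samples=samples, sampling_rate=fs, phase_windows=windows, metadata=meta)


def write_trace_csv(trace: LFPTrace, path) -> Path:
    path = Path(path)
    t = np.arange(len(trace.samples)) / trace.sampling_rate
    pd.DataFrame({"time_s": t, "voltage_mV": trace.samples}).to_csv(path, index=False)
    return path


def read_trace_csv(path, phase_windows: tuple[PhaseWindow, ...] = ()) -> LFPTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace CSV needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return LFPTrace(
        samples=df["voltage_mV"].to_numpy(),
        sampling_rate=fs,
        phase_windows=phase_windows,
    )


def write_stack_tiff(series: IOSSeries, path) -> Path:
    """Multi-page 8-bit grayscale TIFF; timing goes to a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, series.frames.astype(np.uint8), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_times_s": [float(t) for t in series.frame_times_s],
                "n_control_frames": int(series.n_control_frames),
            }
        )
    )
    return path


def read_stack_tiff(
    path,
    frame_rate_hz: float = 2.0,
    n_control_frames: int = 20,
    masks=None,
) -> IOSSeries:
    """Read a stack; timing comes from the sidecar if present, else args."""
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        times = np.asarray(info["frame_times_s"], dtype=float)
        n_control_frames = int(info["n_control_frames"])
    else:
        times = (np.arange(len(frames)) - n_control_frames + 0.5) / frame_rate_hz
    return IOSSeries(
        frames=frames,
        frame_times_s=times,
        n_control_frames=n_control_frames,
        masks=masks,
    )


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    out: list[int] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], flat, [False])).astype(np.int8)))
    for start, end in zip(idx[::2], idx[1::2]):
        out.extend([int(start), int(end - start)])
    return out


def write_masks_json(masks, path) -> Path:
    from .ios_analysis import _as_mask_dict

    path = Path(path)
    table = _as_mask_dict(masks)
    payload = {
        "shape": list(next(iter(table.values())).shape),
        "regions": {label: _rle_encode(m) for label, m in table.items()},
    }
    path.write_text(json.dumps(payload))
    return path


def read_masks_json(path):
    from .synthetic_data.masks import RegionMaskSet

    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    masks = {}
    for label, runs in payload["regions"].items():
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        for start, length in zip(runs[::2], runs[1::2]):
            flat[start : start + length] = True
        masks[label] = flat.reshape(shape)
    return RegionMaskSet(masks=masks)


def write_masks_tiff(masks, path) -> Path:
    import tifffile

    from .ios_analysis import _as_mask_dict

    path = Path(path)
    table = _as_mask_dict(masks)
    label_img = np.zeros(next(iter(table.values())).shape, dtype=np.uint8)
    for i, mask in enumerate(table.values(), start=1):
        label_img[mask] = i
    tifffile.imwrite(path, label_img, photometric="minisblack")
    return path


def events_to_dataframe(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "duration_s": e.duration_s,
                "dc_shift_mV": e.dc_shift_amplitude_mV,
                "ripple_confirmed": e.ripple_confirmed,
                "phase": e.phase_label if e.phase_label is not None else "",
            }
            for e in events
        ],
        columns=[
            "onset_s",
            "offset_s",
            "duration_s",
            "dc_shift_mV",
            "ripple_confirmed",
            "phase",
        ],
    )


def write_events_csv(events, path) -> Path:
    path = Path(path)
    events_to_dataframe(events).to_csv(path, index=False)
    return path


def read_events_csv(path) -> list[SLEEvent]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SLEEvent(
                onset_s=float(row.onset_s),
                offset_s=float(row.offset_s),
                duration_s=float(row.duration_s),
                dc_shift_amplitude_mV=float(row.dc_shift_mV),
                ripple_confirmed=bool(row.ripple_confirmed),
                phase_label=str(row.phase) or None,
            )
        )
    return out


def write_events_json(events, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([asdict(e) for e in events], indent=1))
    return path


def write_ground_truth_json(truth, path) -> Path:
    path = Path(path)
    payload = []
    for e in truth.events:
        rec = {
            "onset_s": e.onset_s,
            "duration_s": e.duration_s,
            "amplitude_mv": e.amplitude_mv,
            "onset_region": e.onset_region,
            "phase_label": e.phase_label,
            "ripple_hz": e.ripple_hz,
        }
        if e.involvement is not None:
            rec["involvement_rle"] = {
                label: _rle_encode(m) for label, m in e.involvement.items()
            }
        payload.append(rec)
    path.write_text(json.dumps(payload))
    return path
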
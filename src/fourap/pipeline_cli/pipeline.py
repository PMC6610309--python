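"""End-to-end orchestration: simulate -> detect -> ios -> stats -> report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import PHASES, __version__
from ..ios_analysis import compute_dtt, involvement_map, roi_intensity, sle_area
from ..lfp_events import (
    PhaseWindow,
    check_slice_inclusion,
    detect_sles,
    remove_drift,
    summarize_phase,
)
from ..pharm_stats import (
    aggregate_group,
    between_group_test,
    build_report,
    compute_slice_effects,
    within_group_test,
)
from ..synthetic_data import build_region_masks, default_group_specs, generate_cohort
from ..synthetic_data.ios import generate_ios_series
from .config import PipelineConfig, config_hash, validate_config

logger = logging.getLogger("fourap.pipeline")

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    version: str
    outputs: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, dict] = field(default_factory=dict)
    excluded_slices: list[dict] = field(default_factory=list)
    started_at: float = 0.0
    finished_at: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "outputs": self.outputs,
                "counts": self.counts,
                "excluded_slices": self.excluded_slices,
                "started_at": self.started_at,
                "finished_at": self.finished_at,
            },
            indent=1,
            sort_keys=True,
        )


def _slice_ios_summaries(
    truth, masks, spec, config: PipelineConfig, rng: np.random.Generator
) -> dict[str, dict[str, dict[str, float]]]:
    """Generate and analyze stacks for the last events of each phase."""
    ios_cfg = config.ios
    out: dict[str, dict[str, dict[str, float]]] = {}
    for phase in PHASES:
        events = truth.in_phase(phase)[-config.ios_events_per_phase :]
        if not events:
            continue
        acc: dict[str, dict[str, list[float]]] = {}
        for event in events:
            series, _ = generate_ios_series(
                event,
                masks,
                spec,
                seed=int(rng.integers(0, 2**31 - 1)),
                frame_rate_hz=ios_cfg.frame_rate_hz,
                n_control_frames=ios_cfg.control_frames,
                roi_size=ios_cfg.roi_size,
            )
            dtt = compute_dtt(series)
            rois = roi_intensity(dtt, masks, roi_size=ios_cfg.roi_size)
            inv = involvement_map(
                dtt,
                threshold_pct=ios_cfg.threshold_pct,
                persistence_frames=ios_cfg.persistence_frames,
            )
            areas = sle_area(inv, masks)
            for region in masks.labels():
                acc.setdefault(region, {"dtt_pct": [], "area_pct": []})
                acc[region]["dtt_pct"].append(rois[region].peak_pct)
                acc[region]["area_pct"].append(areas[region])
        out[phase] = {
            region: {
                "dtt_pct": float(np.mean(vals["dtt_pct"])),
                "area_pct": float(np.mean(vals["area_pct"])),
            }
            for region, vals in acc.items()
        }
    return out


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    with_ios: bool = True,
) -> RunManifest:
    """Run every stage; identical config+seed gives identical summary tables.

    Raises
    ------
    PipelineError
        On stage failure (partial outputs are retained in ``out_dir``).
    ValueError
        On an invalid configuration.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config), version=__version__, started_at=time.time()
    )
    (out_dir / "config.yaml").write_text(config.to_yaml())

    specs = default_group_specs()
    masks = build_region_masks()
    effects_by_group: dict[str, list] = {}
    ratios_by_group: dict[str, list[float]] = {}
    rows = []

    seed_seq = np.random.SeedSequence(config.seed)
    group_seeds = {
        label: child
        for label, child in zip(config.resolved_groups(), seed_seq.spawn(len(config.resolved_groups())))
    }

    for label in config.resolved_groups():
        spec = specs[label]
        n = config.n_slices.get(label, spec.n_slices_reported)
        group_seed = int(np.random.default_rng(group_seeds[label]).integers(0, 2**31 - 1))
        try:
            cohort = generate_cohort(
                spec, n, seed=group_seed, sampling_rate=config.sampling_rate_hz
            )
        except Exception as exc:  # pragma: no cover
            raise PipelineError("simulate", f"group {label}: {exc}") from exc

        effects = []
        ios_rng = np.random.default_rng(group_seeds[label].spawn(1)[0])
        for exp in cohort:
            try:
                trace, truth = exp.generate()
                trace = remove_drift(trace, cutoff_hz=config.drift_cutoff_hz)
                events = detect_sles(trace, config.detection)
            except Exception as exc:
                raise PipelineError("detect", f"slice {exp.slice_id}: {exc}") from exc
            if not check_slice_inclusion(
                events, fourap_start_s=0.0, limit_min=config.inclusion_limit_min
            ):
                manifest.excluded_slices.append(
                    {"slice_id": exp.slice_id, "reason": "no SLE within 45 min"}
                )
                logger.info("excluding %s: no SLE within 45 min", exp.slice_id)
                continue
            summaries = {
                w.label: summarize_phase(events, w, k=config.stats.k_events)
                for w in trace.phase_windows
            }
            ios_summaries = None
            if with_ios:
                try:
                    ios_summaries = _slice_ios_summaries(
                        truth, masks, exp.spec, config, ios_rng
                    )
                except Exception as exc:
                    raise PipelineError("ios", f"slice {exp.slice_id}: {exc}") from exc
            try:
                eff = compute_slice_effects(
                    summaries,
                    slice_id=exp.slice_id,
                    animal_id=exp.animal_id,
                    group_label=label,
                    ios_summaries=ios_summaries,
                )
            except ValueError:
                manifest.excluded_slices.append(
                    {"slice_id": exp.slice_id, "reason": "zero baseline frequency"}
                )
                continue
            effects.append(eff)
            row = {
                "group": label,
                "slice_id": exp.slice_id,
                "frequency_ratio": eff.frequency_ratio,
                "duration_ratio": eff.duration_ratio,
                "amplitude_ratio": eff.amplitude_ratio,
                "responder": eff.responder,
                "n_events": sum(
                    s.n_events_total for s in eff.phase_summaries.values()
                ),
            }
            for phase, s in eff.phase_summaries.items():
                row[f"freq_{phase}"] = s.sle_frequency_per_min
                row[f"dur_{phase}"] = s.mean_duration_s
                row[f"dc_{phase}"] = s.mean_dc_shift_mV
            rows.append(row)
        if not effects:
            raise PipelineError("stats", f"group {label}: every slice excluded")
        effects_by_group[label] = effects
        ratios_by_group[label] = [e.frequency_ratio for e in effects]
        manifest.counts[label] = {
            "slices_generated": n,
            "slices_included": len(effects),
            "events_detected": int(
                sum(r["n_events"] for r in rows if r["group"] == label)
            ),
        }
        logger.info(
            "group %s: %d/%d slices included", label, len(effects), n
        )

    slice_csv = out_dir / "slice_effects.csv"
    pd.DataFrame(rows).to_csv(slice_csv, index=False)
    manifest.outputs["slices"] = [str(slice_csv)]

    try:
        group_results = []
        stats_blob: dict[str, dict] = {}
        for label, effects in effects_by_group.items():
            g = aggregate_group(effects)
            if len(effects) >= 3:
                g.within["sle_frequency_per_min"] = within_group_test(effects)
            group_results.append(g)
        if len(effects_by_group) >= 2 and "control" in effects_by_group:
            bg = between_group_test(
                ratios_by_group, control_label="control", alpha=config.stats.alpha
            )
            for g in group_results:
                g.adjusted_p_vs_control = bg.adjusted_p_vs_control.get(
                    g.group_label, float("nan")
                )
            stats_blob["between_groups"] = {
                "anova_p": bg.anova_p,
                "adjusted_p_vs_control": bg.adjusted_p_vs_control,
            }
        for g in group_results:
            stats_blob[g.group_label] = {
                "n_slices": g.n_slices,
                "mean_frequency_ratio": g.mean_frequency_ratio,
                "responder_rate": g.responder_rate,
                "within": {
                    m: {
                        "method": w.method,
                        "anova_p": w.anova_p,
                        "p_intervention_vs_baseline": w.p_intervention_vs_baseline,
                        "p_washout_vs_baseline": w.p_washout_vs_baseline,
                    }
                    for m, w in g.within.items()
                },
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    stats_path = out_dir / "stats.json"
    stats_path.write_text(json.dumps(stats_blob, indent=1, sort_keys=True, default=float))
    manifest.outputs["stats"] = [str(stats_path)]

    try:
        written = build_report(group_results, effects_by_group, out_dir / "report")
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    manifest.outputs["report"] = sorted(written.values())

    manifest.finished_at = time.time()
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
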
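"""Cohort generation: per-slice seeds and parameter jitter around group means."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .. import PHASES
from ..lfp_events import LFPTrace
from .lfp import GroundTruth, generate_lfp
from .specs import GroupSpec

__all__ = ["SliceExperiment", "generate_cohort"]


@dataclass
class SliceExperiment:
    """One simulated slice: jittered spec plus a deterministic trace seed.

    Traces are rendered lazily via :meth:`generate` so that large cohorts
    do not have to be held in memory at once.
    """

    slice_id: str
    animal_id: str
    group_label: str
    spec: GroupSpec
    seed: int
    sampling_rate: float
    phases: tuple[str, ...]

    def generate(self) -> tuple[LFPTrace, GroundTruth]:
        trace, truth = generate_lfp(
            self.spec,
            seed=self.seed,
            sampling_rate=self.sampling_rate,
            phases=self.phases,
            metadata={"slice_id": self.slice_id, "animal_id": self.animal_id},
        )
        return trace, truth


def _jitter_spec(spec: GroupSpec, rng: np.random.Generator) -> GroupSpec:
    """Per-slice parameters drawn around the group means, physically bounded."""

    def trunc(mean, sd, lower):
        return float(max(rng.normal(mean, sd), lower))

    rate = trunc(spec.baseline_rate_per_min, spec.baseline_rate_sd, 0.03)
    ri = spec.rate_ratio_intervention
    if ri > 0:
        ri = trunc(ri, spec.rate_ratio_sd, 0.0)
    rw = spec.rate_ratio_washout
    if rw > 0:
        rw = trunc(rw, spec.rate_ratio_sd, 0.0)
    durations = tuple(
        trunc(m, spec.duration_slice_sd_s, 20.0) for m in spec.duration_mean_s
    )
    amplitudes = tuple(
        trunc(m, spec.dc_amplitude_slice_sd_mv, 0.7)
        for m in spec.dc_amplitude_mean_mv
    )
    return spec.with_overrides(
        baseline_rate_per_min=rate,
        rate_ratio_intervention=ri,
        rate_ratio_washout=rw,
        duration_mean_s=durations,
        dc_amplitude_mean_mv=amplitudes,
    )


def generate_cohort(
    spec: GroupSpec,
    n_slices: int,
    seed: int,
    sampling_rate: float = 5000.0,
    phases: Sequence[str] = PHASES,
    jitter: bool = True,
) -> list[SliceExperiment]:
    """Deterministically derive ``n_slices`` independent slice experiments.

    Per-slice seeds are spawned from the master seed; per-slice parameters
    are jittered around the group means (disable with ``jitter=False``).

    Raises
    ------
    ValueError
        If ``n_slices`` is less than 1.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_slices)
    experiments = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        slice_spec = _jitter_spec(spec, rng) if jitter else spec
        trace_seed = int(rng.integers(0, 2**31 - 1))
        experiments.append(
            SliceExperiment(
                slice_id=f"{spec.group_label}_s{i:02d}",
                animal_id=f"{spec.group_label}_a{i:02d}",
                group_label=spec.group_label,
                spec=slice_spec,
                seed=trace_seed,
                sampling_rate=float(sampling_rate),
                phases=tuple(phases),
            )
        )
    return experiments
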
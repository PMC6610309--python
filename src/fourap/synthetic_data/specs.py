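"""Experimental-arm parameter tables for the synthetic generator.

Each :class:`GroupSpec` bundles every parameter needed to simulate one
experimental arm (control or drug/dose): per-phase event rates, event
duration and DC-shift distributions, per-region optical amplitudes and
involvement fractions, and wash-out behavior.  The numbers returned by
:func:`default_group_specs` are the published group means of the underlying
study; parameters the study does not report (spreads, unaffected regions)
are set to plausible values inside the reported ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .. import PHASES, REGIONS

__all__ = ["GroupSpec", "default_group_specs"]

PhaseTriple = tuple[float, float, float]


def _flat(value: float) -> PhaseTriple:
    return (value, value, value)


def _region_table(**per_region: PhaseTriple) -> dict[str, PhaseTriple]:
    table = {}
    for region in REGIONS:
        table[region] = per_region.get(region, _flat(0.0))
    return table


@dataclass(frozen=True)
class GroupSpec:
    """Ground-truth parameters for one experimental arm.

    Per-phase triples are ordered (baseline, intervention, wash-out).
    Event rates during intervention and wash-out are derived from the
    baseline rate via the two ratio fields.
    """

    group_label: str
    drug: str  # "none", "LAC", "ZNS" or "LEV"
    concentration_um: float
    n_slices_reported: int
    baseline_rate_per_min: float
    rate_ratio_intervention: float
    rate_ratio_washout: float
    duration_mean_s: PhaseTriple
    dc_amplitude_mean_mv: PhaseTriple
    ios_peak_dtt_pct: Mapping[str, PhaseTriple]
    area_fraction_pct: Mapping[str, PhaseTriple]
    phase_durations_min: PhaseTriple = (60.0, 60.0, 60.0)
    baseline_rate_sd: float = 0.03
    rate_ratio_sd: float = 0.10
    duration_sd_s: float = 8.0
    duration_slice_sd_s: float = 3.0
    dc_amplitude_sd_mv: float = 0.30
    dc_amplitude_slice_sd_mv: float = 0.12
    onset_region_weights: Mapping[str, float] = field(
        default_factory=lambda: {"SUB": 0.05, "EC": 0.45, "PC": 0.15, "TC": 0.35}
    )
    persistent_effect: bool = False

    def __post_init__(self) -> None:
        if self.baseline_rate_per_min < 0:
            raise ValueError("baseline rate must be >= 0")
        if self.rate_ratio_intervention < 0 or self.rate_ratio_washout < 0:
            raise ValueError("rate ratios must be >= 0")
        for d in self.phase_durations_min:
            if not 40.0 <= d <= 60.0:
                raise ValueError("phase durations must lie within [40, 60] min")
        wsum = sum(self.onset_region_weights.values())
        if abs(wsum - 1.0) > 1e-6:
            raise ValueError("onset_region_weights must sum to 1")
        for region, triple in self.area_fraction_pct.items():
            for a in triple:
                if not 0.0 <= a <= 100.0:
                    raise ValueError(
                        f"area fraction for {region} must lie in [0, 100]"
                    )

    @property
    def event_rate_per_phase(self) -> dict[str, float]:
        """Events per minute for each protocol phase."""
        r = self.baseline_rate_per_min
        return {
            "baseline": r,
            "intervention": r * self.rate_ratio_intervention,
            "washout": r * self.rate_ratio_washout,
        }

    def phase_index(self, phase_label: str) -> int:
        return PHASES.index(phase_label)

    def with_overrides(self, **kwargs) -> "GroupSpec":
        return replace(self, **kwargs)


# Optical defaults for regions/arms without a reported drug effect; values
# sit inside the 0.4-4 % dT/T working range of the method.
_DTT_DEFAULTS = {
    "SUB": _flat(1.20),
    "EC": _flat(2.10),
    "PC": _flat(1.80),
    "TC": _flat(1.60),
}
_AREA_DEFAULTS = {
    "SUB": _flat(60.0),
    "EC": _flat(80.0),
    "PC": _flat(70.0),
    "TC": _flat(55.0),
}


def _ios_tables(
    dtt_overrides: Mapping[str, PhaseTriple] | None = None,
    area_overrides: Mapping[str, PhaseTriple] | None = None,
) -> tuple[dict[str, PhaseTriple], dict[str, PhaseTriple]]:
    dtt = dict(_DTT_DEFAULTS)
    area = dict(_AREA_DEFAULTS)
    if dtt_overrides:
        dtt.update(dtt_overrides)
    if area_overrides:
        area.update(area_overrides)
    return dtt, area


def default_group_specs() -> dict[str, GroupSpec]:
    """Control plus nine drug/dose arms with the reported group means.

    Frequency: control baseline 0.17 /min falling to 0.15 in the second and
    third hours; intervention/baseline frequency ratios 0.54 (LAC 33), 0
    (LAC 100, full block), 0.56 (ZNS 100), 0 (ZNS 300), 0.66 (LEV 300).
    Durations: control 53.3/56.9/52.5 s, ZNS 33 60.1/68.1/60.6 s,
    LEV 300 58.2/46.2/37.7 s.  DC shift: control 1.64/1.52/1.43 mV.
    Subiculum optics: LAC 10 dT/T 1.43->1.13 %, area 70.9->61.7 %;
    LAC 33 dT/T 1.10->0.38 %, area 58.9->37.8 %; ZNS 100 dT/T
    1.17->0.78 %, area 51.3->40.2 %.  Temporal cortex, LEV 300: area
    54.8->37.6 %.  Zonisamide effects persist into wash-out.  Ratios not
    reported for an arm are interpolated between its neighbours.
    """
    specs: dict[str, GroupSpec] = {}

    def add(spec: GroupSpec) -> None:
        specs[spec.group_label] = spec

    dtt, area = _ios_tables()
    add(
        GroupSpec(
            group_label="control",
            drug="none",
            concentration_um=0.0,
            n_slices_reported=22,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.90,
            rate_ratio_washout=0.88,
            duration_mean_s=(53.3, 56.9, 52.5),
            dc_amplitude_mean_mv=(1.64, 1.52, 1.43),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    dtt, area = _ios_tables(
        {"SUB": (1.43, 1.13, 1.38)}, {"SUB": (70.9, 61.7, 69.0)}
    )
    add(
        GroupSpec(
            group_label="LAC_10",
            drug="LAC",
            concentration_um=10.0,
            n_slices_reported=13,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.72,
            rate_ratio_washout=0.92,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=_flat(1.55),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    dtt, area = _ios_tables(
        {"SUB": (1.10, 0.38, 1.02)}, {"SUB": (58.9, 37.8, 55.0)}
    )
    add(
        GroupSpec(
            group_label="LAC_33",
            drug="LAC",
            concentration_um=33.0,
            n_slices_reported=10,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.54,
            rate_ratio_washout=0.92,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=(1.60, 1.45, 1.38),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    dtt, area = _ios_tables()
    add(
        GroupSpec(
            group_label="LAC_100",
            drug="LAC",
            concentration_um=100.0,
            n_slices_reported=5,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.0,  # full SLE block
            rate_ratio_washout=0.90,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=_flat(1.55),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    dtt, area = _ios_tables()
    add(
        GroupSpec(
            group_label="ZNS_33",
            drug="ZNS",
            concentration_um=33.0,
            n_slices_reported=10,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.65,
            rate_ratio_washout=0.78,
            duration_mean_s=(60.1, 68.1, 60.6),
            dc_amplitude_mean_mv=(1.60, 1.48, 1.40),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
            persistent_effect=True,
        )
    )

    dtt, area = _ios_tables(
        {"SUB": (1.17, 0.78, 1.10)}, {"SUB": (51.3, 40.2, 49.0)}
    )
    add(
        GroupSpec(
            group_label="ZNS_100",
            drug="ZNS",
            concentration_um=100.0,
            n_slices_reported=13,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.56,
            rate_ratio_washout=0.75,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=_flat(1.50),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
            persistent_effect=True,
        )
    )

    dtt, area = _ios_tables()
    add(
        GroupSpec(
            group_label="ZNS_300",
            drug="ZNS",
            concentration_um=300.0,
            n_slices_reported=5,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.0,  # full SLE block
            rate_ratio_washout=0.62,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=_flat(1.55),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
            persistent_effect=True,
        )
    )

    dtt, area = _ios_tables()
    add(
        GroupSpec(
            group_label="LEV_33",
            drug="LEV",
            concentration_um=33.0,
            n_slices_reported=9,
            baseline_rate_per_min=0.16,
            rate_ratio_intervention=0.81,  # 0.13 of 0.16 /min
            rate_ratio_washout=0.90,
            baseline_rate_sd=0.02,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=_flat(1.50),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    dtt, area = _ios_tables()
    add(
        GroupSpec(
            group_label="LEV_100",
            drug="LEV",
            concentration_um=100.0,
            n_slices_reported=11,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.75,
            rate_ratio_washout=0.90,
            duration_mean_s=_flat(55.0),
            dc_amplitude_mean_mv=_flat(1.50),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    dtt, area = _ios_tables(area_overrides={"TC": (54.8, 37.6, 45.0)})
    add(
        GroupSpec(
            group_label="LEV_300",
            drug="LEV",
            concentration_um=300.0,
            n_slices_reported=11,
            baseline_rate_per_min=0.17,
            rate_ratio_intervention=0.66,
            rate_ratio_washout=0.85,
            duration_mean_s=(58.2, 46.2, 37.7),
            dc_amplitude_mean_mv=(1.55, 1.45, 1.35),
            ios_peak_dtt_pct=dtt,
            area_fraction_pct=area,
        )
    )

    return specs
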
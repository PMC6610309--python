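"""Drug-effect aggregation, responder rates and group statistics.

Per-slice effect ratios relate the intervention phase to baseline (for the
control group the "intervention" column is simply its second hour).  The
repeated-measures comparison across the three phases uses a linear mixed
model with a slice-level random intercept and Tukey-adjusted pairwise
contrasts; when a drug blocks events completely in every slice the
intervention column is empty and a two-sided paired t-test compares
baseline against wash-out instead.  Between-group comparisons use one-way
ANOVA with control-vs-drug t-tests adjusted by the Benjamini-Yekutieli
false discovery rate procedure.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import PHASES, REGIONS
from .lfp_events import PhaseSummary

__all__ = [
    "SliceEffect",
    "GroupResult",
    "WithinGroupResult",
    "BetweenGroupResult",
    "compute_slice_effects",
    "within_group_test",
    "between_group_test",
    "baseline_effect_correlation",
    "responder_rate",
    "aggregate_group",
    "build_report",
]

RESPONDER_RATIO_CUTOFF = 0.5  # >= 50 % frequency reduction


@dataclass
class SliceEffect:
    """Per-slice phase summaries and derived intervention/baseline ratios."""

    slice_id: str
    group_label: str
    phase_summaries: dict[str, PhaseSummary]
    animal_id: str = ""
    ios_summaries: dict[str, dict[str, dict[str, float]]] | None = None
    frequency_ratio: float = float("nan")
    duration_ratio: float = float("nan")
    amplitude_ratio: float = float("nan")
    dtt_ratio: dict[str, float] = field(default_factory=dict)
    area_ratio: dict[str, float] = field(default_factory=dict)
    responder: bool = False


def _safe_ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return float("nan")
    return float(num / den)


def compute_slice_effects(
    phase_summaries: Mapping[str, PhaseSummary],
    slice_id: str = "",
    group_label: str = "",
    animal_id: str = "",
    ios_summaries: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
) -> SliceEffect:
    """Derive ratios and the responder flag for one slice.

    ``ios_summaries`` maps phase -> region -> ``{"dtt_pct":…, "area_pct":…}``;
    missing entries (e.g. a full block leaves nothing to image) yield NaN
    ratios rather than imputed values.

    Raises
    ------
    ValueError
        If baseline frequency is zero — such a slice violates the 45-min
        inclusion rule and must not enter the analysis.
    """
    base = phase_summaries["baseline"]
    inter = phase_summaries["intervention"]
    if base.sle_frequency_per_min == 0:
        raise ValueError(
            "baseline SLE frequency is zero; slice violates the 45-min "
            "inclusion rule and must be excluded"
        )
    freq_ratio = inter.sle_frequency_per_min / base.sle_frequency_per_min
    eff = SliceEffect(
        slice_id=slice_id,
        animal_id=animal_id,
        group_label=group_label,
        phase_summaries=dict(phase_summaries),
        ios_summaries=dict(ios_summaries) if ios_summaries is not None else None,
        frequency_ratio=float(freq_ratio),
        duration_ratio=_safe_ratio(inter.mean_duration_s, base.mean_duration_s),
        amplitude_ratio=_safe_ratio(inter.mean_dc_shift_mV, base.mean_dc_shift_mV),
        responder=freq_ratio <= RESPONDER_RATIO_CUTOFF,
    )
    if ios_summaries is not None:
        base_ios = ios_summaries.get("baseline", {})
        inter_ios = ios_summaries.get("intervention", {})
        for region in base_ios:
            b = base_ios.get(region, {})
            i = inter_ios.get(region, {})
            eff.dtt_ratio[region] = _safe_ratio(
                i.get("dtt_pct", float("nan")), b.get("dtt_pct", float("nan"))
            )
            eff.area_ratio[region] = _safe_ratio(
                i.get("area_pct", float("nan")), b.get("area_pct", float("nan"))
            )
    return eff


@dataclass(frozen=True)
class WithinGroupResult:
    metric: str
    method: str  # "mixed_model", "paired_t" or "full_block_paired_t"
    anova_p: float
    p_intervention_vs_baseline: float
    p_washout_vs_baseline: float
    p_washout_vs_intervention: float
    full_block: bool = False


def _metric_value(summary: PhaseSummary, metric: str) -> float:
    return float(getattr(summary, metric))


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    if np.allclose(d, 0):
        return 1.0
    return float(sps.ttest_rel(a, b).pvalue)


def _tukey_p(t_stat: float, k: int, df: int) -> float:
    if not np.isfinite(t_stat):
        return 1.0
    return float(sps.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, max(df, 2)))


def within_group_test(
    effects: Sequence[SliceEffect],
    metric: str = "sle_frequency_per_min",
) -> WithinGroupResult:
    """Repeated-measures comparison of a metric across the three phases.

    Raises
    ------
    ValueError
        With fewer than 3 slices or missing phases.
    """
    if len(effects) < 3:
        raise ValueError("within-group test needs at least 3 slices")
    for eff in effects:
        for phase in PHASES:
            if phase not in eff.phase_summaries:
                raise ValueError(f"slice {eff.slice_id!r} lacks phase {phase!r}")

    values = {
        phase: np.array(
            [_metric_value(e.phase_summaries[phase], metric) for e in effects]
        )
        for phase in PHASES
    }

    if metric == "sle_frequency_per_min" and np.all(values["intervention"] == 0):
        # full SLE block: nothing to compare during intervention
        p_bw = _paired_p(values["baseline"], values["washout"])
        return WithinGroupResult(
            metric=metric,
            method="full_block_paired_t",
            anova_p=float("nan"),
            p_intervention_vs_baseline=float("nan"),
            p_washout_vs_baseline=p_bw,
            p_washout_vs_intervention=float("nan"),
            full_block=True,
        )

    df = pd.DataFrame(
        {
            "value": np.concatenate([values[p] for p in PHASES]),
            "phase": np.repeat(PHASES, len(effects)),
            "slice_id": np.tile([e.slice_id or str(i) for i, e in enumerate(effects)], 3),
        }
    ).dropna(subset=["value"])

    n = len(effects)
    dof = max(2 * (n - 1), 2)
    try:
        if df["value"].std() == 0:
            raise ValueError("zero variance")
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ C(phase, Treatment('baseline'))", df, groups=df["slice_id"]
            )
            res = model.fit(reml=True)
        names = list(res.params.index)
        ci = names.index("C(phase, Treatment('baseline'))[T.intervention]")
        cw = names.index("C(phase, Treatment('baseline'))[T.washout]")
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())

        def contrast(i, j=None):
            if j is None:
                est, var = params[i], cov[i, i]
            else:
                est = params[i] - params[j]
                var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            return est / np.sqrt(max(var, 1e-30))

        p_ib = _tukey_p(contrast(ci), 3, dof)
        p_wb = _tukey_p(contrast(cw), 3, dof)
        p_wi = _tukey_p(contrast(cw, ci), 3, dof)
        wald = res.wald_test(
            "C(phase, Treatment('baseline'))[T.intervention] = 0, "
            "C(phase, Treatment('baseline'))[T.washout] = 0",
            scalar=True,
        )
        anova_p = float(wald.pvalue)
        method = "mixed_model"
    except Exception:
        # small-n / degenerate fallback: paired t-tests
        p_ib = _paired_p(values["intervention"], values["baseline"])
        p_wb = _paired_p(values["washout"], values["baseline"])
        p_wi = _paired_p(values["washout"], values["intervention"])
        anova_p = min(1.0, 3.0 * min(p_ib, p_wb, p_wi))
        method = "paired_t"

    return WithinGroupResult(
        metric=metric,
        method=method,
        anova_p=anova_p,
        p_intervention_vs_baseline=p_ib,
        p_washout_vs_baseline=p_wb,
        p_washout_vs_intervention=p_wi,
    )


@dataclass(frozen=True)
class BetweenGroupResult:
    metric: str
    anova_p: float
    raw_p_vs_control: dict[str, float]
    adjusted_p_vs_control: dict[str, float]
    alpha: float = 0.05


def between_group_test(
    ratios_by_group: Mapping[str, Sequence[float]],
    control_label: str = "control",
    alpha: float = 0.05,
) -> BetweenGroupResult:
    """Omnibus one-way ANOVA plus BY-FDR-adjusted t-tests vs control only.

    Raises
    ------
    ValueError
        With fewer than 2 groups or a missing control group.
    """
    groups = {
        k: np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        for k, vals in ratios_by_group.items()
    }
    if len(groups) < 2:
        raise ValueError("between-group test needs at least 2 groups")
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    anova_p = float(sps.f_oneway(*groups.values()).pvalue)
    control = groups[control_label]
    labels = [k for k in groups if k != control_label]
    raw = {}
    for label in labels:
        raw[label] = float(sps.ttest_ind(groups[label], control).pvalue)
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([raw[l] for l in labels], alpha=alpha, method="fdr_by")[1]
    return BetweenGroupResult(
        metric="ratio",
        anova_p=anova_p,
        raw_p_vs_control=raw,
        adjusted_p_vs_control=dict(zip(labels, (float(p) for p in adj))),
        alpha=alpha,
    )


def baseline_effect_correlation(
    baseline_values: Sequence[float],
    ratios: Sequence[float],
) -> tuple[float, float]:
    """Pearson r (two-sided p) between baseline level and relative effect."""
    x = np.asarray(baseline_values, dtype=float)
    y = np.asarray(ratios, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 paired observations")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def responder_rate(effects: Sequence[SliceEffect]) -> float:
    """Fraction of slices with a >= 50 % frequency reduction (all slices count)."""
    if not effects:
        raise ValueError("no slices")
    return sum(1 for e in effects if e.responder) / len(effects)


@dataclass
class GroupResult:
    group_label: str
    n_slices: int
    mean_sd: dict[str, dict[str, tuple[float, float]]]  # metric -> phase -> (m, sd)
    mean_frequency_ratio: float
    mean_duration_ratio: float
    mean_amplitude_ratio: float
    responder_rate: float
    within: dict[str, WithinGroupResult] = field(default_factory=dict)
    adjusted_p_vs_control: float = float("nan")


def _nanmean(values) -> float:
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).any():
        return float("nan")
    return float(np.nanmean(values))


def aggregate_group(effects: Sequence[SliceEffect]) -> GroupResult:
    """Mean +/- SD per metric and phase plus mean ratios and responder rate."""
    if not effects:
        raise ValueError("no slices in group")
    metrics = ("sle_frequency_per_min", "mean_duration_s", "mean_dc_shift_mV")
    mean_sd: dict[str, dict[str, tuple[float, float]]] = {}
    for metric in metrics:
        mean_sd[metric] = {}
        for phase in PHASES:
            vals = np.array(
                [_metric_value(e.phase_summaries[phase], metric) for e in effects]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                mean_sd[metric][phase] = (
                    _nanmean(vals),
                    float(np.nanstd(vals, ddof=1)) if np.isfinite(vals).sum() > 1 else float("nan"),
                )
    return GroupResult(
        group_label=effects[0].group_label,
        n_slices=len(effects),
        mean_sd=mean_sd,
        mean_frequency_ratio=_nanmean([e.frequency_ratio for e in effects]),
        mean_duration_ratio=_nanmean([e.duration_ratio for e in effects]),
        mean_amplitude_ratio=_nanmean([e.amplitude_ratio for e in effects]),
        responder_rate=responder_rate(effects),
    )


def group_summary_table(results: Sequence[GroupResult]) -> pd.DataFrame:
    rows = []
    for g in results:
        row = {
            "group": g.group_label,
            "n_slices": g.n_slices,
            "frequency_ratio": g.mean_frequency_ratio,
            "duration_ratio": g.mean_duration_ratio,
            "amplitude_ratio": g.mean_amplitude_ratio,
            "responder_rate": g.responder_rate,
            "adjusted_p_vs_control": g.adjusted_p_vs_control,
        }
        for metric, phases in g.mean_sd.items():
            for phase, (m, sd) in phases.items():
                row[f"{metric}.{phase}.mean"] = m
                row[f"{metric}.{phase}.sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(
    group_results: Sequence[GroupResult],
    effects_by_group: Mapping[str, Sequence[SliceEffect]],
    out_dir,
) -> dict[str, str]:
    """Write summary CSV and overview figures; returns written file paths.

    Raises
    ------
    ValueError
        On an empty group list.
    """
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not group_results:
        raise ValueError("no group results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    table = group_summary_table(group_results)
    csv_path = out_dir / "group_summary.csv"
    table.to_csv(csv_path, index=False)
    written["summary_csv"] = str(csv_path)

    # per-group frequency over phases: scatter + mean +/- SD
    ncols = min(len(group_results), 5)
    nrows = int(np.ceil(len(group_results) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.0 * ncols, 2.6 * nrows), squeeze=False, sharey=True
    )
    xs = np.arange(len(PHASES))
    for ax, g in zip(axes.ravel(), group_results):
        effects = effects_by_group[g.group_label]
        for e in effects:
            ax.plot(
                xs + np.random.default_rng(
                    zlib.crc32(e.slice_id.encode())
                ).uniform(-0.08, 0.08),
                [e.phase_summaries[p].sle_frequency_per_min for p in PHASES],
                "o",
                ms=3,
                alpha=0.4,
                color="gray",
            )
        means = [g.mean_sd["sle_frequency_per_min"][p][0] for p in PHASES]
        sds = [g.mean_sd["sle_frequency_per_min"][p][1] for p in PHASES]
        ax.errorbar(xs, means, yerr=sds, color="C0", capsize=3, lw=2)
        ax.set_xticks(xs, PHASES, rotation=30, fontsize=7)
        ax.set_title(g.group_label, fontsize=9)
    for ax in axes.ravel()[len(group_results) :]:
        ax.axis("off")
    axes[0, 0].set_ylabel("SLE / min")
    fig.tight_layout()
    freq_path = out_dir / "frequency_by_phase.png"
    fig.savefig(freq_path, dpi=120)
    plt.close(fig)
    written["frequency_figure"] = str(freq_path)

    # frequency-ratio scatter and responder-rate bars
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(1.0 + 0.9 * len(group_results), 5.5))
    for i, g in enumerate(group_results):
        ratios = [e.frequency_ratio for e in effects_by_group[g.group_label]]
        ax1.plot(np.full(len(ratios), i), ratios, "o", ms=4, alpha=0.5, color="C0")
        ax1.plot([i - 0.2, i + 0.2], [g.mean_frequency_ratio] * 2, color="k")
        ax2.bar(i, g.responder_rate, color="C1")
    labels = [g.group_label for g in group_results]
    for ax in (ax1, ax2):
        ax.set_xticks(range(len(labels)), labels, rotation=45, fontsize=7)
    ax1.set_ylabel("frequency ratio")
    ax2.set_ylabel("responder rate")
    ax2.set_ylim(0, 1.05)
    fig.tight_layout()
    ratio_path = out_dir / "ratios_and_responders.png"
    fig.savefig(ratio_path, dpi=120)
    plt.close(fig)
    written["ratio_figure"] = str(ratio_path)
    return written
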
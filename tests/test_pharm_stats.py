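import numpy as np
import pytest

from fourap.lfp_events import PhaseSummary
from fourap.pharm_stats import (
    aggregate_group,
    baseline_effect_correlation,
    between_group_test,
    build_report,
    compute_slice_effects,
    group_summary_table,
    responder_rate,
    within_group_test,
)

PHASES = ("baseline", "intervention", "washout")


def summaries_from_freqs(freqs, duration=55.0, amp=1.5):
    # a phase without events carries NaN means, as summarize_phase would
    return {
        phase: PhaseSummary(
            phase,
            f,
            duration if f > 0 else float("nan"),
            amp if f > 0 else float("nan"),
            int(round(f * 60)),
            min(5, int(round(f * 60))),
        )
        for phase, f in zip(PHASES, freqs)
    }


def make_effects(n, ratio, rng=None, full_block=False, washout=0.9):
    rng = rng or np.random.default_rng(0)
    effects = []
    for i in range(n):
        base = max(rng.normal(0.17, 0.03), 0.05)
        inter = 0.0 if full_block else base * max(rng.normal(ratio, 0.1), 0.0)
        wash = base * max(rng.normal(washout, 0.1), 0.0)
        effects.append(
            compute_slice_effects(
                summaries_from_freqs((base, inter, wash)),
                slice_id=f"s{i}",
                group_label="test",
            )
        )
    return effects


class TestComputeSliceEffects:
    def test_half_ratio_is_responder(self):
        eff = compute_slice_effects(summaries_from_freqs((0.16, 0.08, 0.15)))
        assert eff.frequency_ratio == pytest.approx(0.5)
        assert eff.responder is True

    def test_full_block_ratio_zero_responder(self):
        eff = compute_slice_effects(summaries_from_freqs((0.16, 0.0, 0.12)))
        assert eff.frequency_ratio == 0.0
        assert eff.responder is True
        assert np.isnan(eff.duration_ratio)  # no events to measure

    def test_weak_effect_not_responder(self):
        eff = compute_slice_effects(summaries_from_freqs((0.16, 0.12, 0.15)))
        assert eff.frequency_ratio == pytest.approx(0.75)
        assert eff.responder is False

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="inclusion"):
            compute_slice_effects(summaries_from_freqs((0.0, 0.1, 0.1)))

    def test_ios_ratios(self):
        ios = {
            "baseline": {"SUB": {"dtt_pct": 1.0, "area_pct": 50.0}},
            "intervention": {"SUB": {"dtt_pct": 0.5, "area_pct": 25.0}},
        }
        eff = compute_slice_effects(
            summaries_from_freqs((0.16, 0.08, 0.15)), ios_summaries=ios
        )
        assert eff.dtt_ratio["SUB"] == pytest.approx(0.5)
        assert eff.area_ratio["SUB"] == pytest.approx(0.5)

    def test_missing_ios_marked_nan(self):
        ios = {
            "baseline": {"SUB": {"dtt_pct": 1.0, "area_pct": 50.0}},
            "intervention": {},
        }
        eff = compute_slice_effects(
            summaries_from_freqs((0.16, 0.0, 0.15)), ios_summaries=ios
        )
        assert np.isnan(eff.dtt_ratio["SUB"])


class TestWithinGroupTest:
    def test_identical_values_p_near_one(self):
        effects = [
            compute_slice_effects(summaries_from_freqs((0.15, 0.15, 0.15)), slice_id=f"s{i}")
            for i in range(5)
        ]
        res = within_group_test(effects)
        assert res.p_intervention_vs_baseline == pytest.approx(1.0)

    def test_full_block_uses_paired_t(self):
        effects = make_effects(5, 0.0, full_block=True)
        res = within_group_test(effects)
        assert res.full_block
        assert res.method == "full_block_paired_t"
        assert np.isfinite(res.p_washout_vs_baseline)
        assert np.isnan(res.p_intervention_vs_baseline)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            within_group_test(make_effects(2, 0.5))

    def test_missing_phase_rejected(self):
        eff = compute_slice_effects(summaries_from_freqs((0.15, 0.1, 0.12)))
        del eff.phase_summaries["washout"]
        with pytest.raises(ValueError, match="lacks phase"):
            within_group_test([eff] * 3)

    def test_power_on_strong_effect(self):
        # LAC-33-like effect (ratio 0.54, n=10): significant in >=90 % of cohorts
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            res = within_group_test(make_effects(10, 0.54, rng=rng))
            if res.p_intervention_vs_baseline < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_duration_metric(self):
        effects = make_effects(6, 0.5)
        res = within_group_test(effects, metric="mean_duration_s")
        assert res.p_intervention_vs_baseline == pytest.approx(1.0, abs=0.2)


class TestBetweenGroupTest:
    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            between_group_test({"control": [0.9, 0.8]})

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            between_group_test({"a": [1, 2], "b": [2, 3]})

    def test_type_one_error_near_nominal(self):
        # all groups drawn from one distribution: rejection rate ~ alpha
        rng = np.random.default_rng(0)
        n_rep = 500
        rejections = 0
        for _ in range(n_rep):
            groups = {
                label: rng.normal(0.8, 0.15, 8)
                for label in ("control", "g1", "g2")
            }
            if between_group_test(groups).anova_p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 2.5 * se

    def test_power_against_full_block(self):
        # control vs complete suppression: adjusted p < 0.05 in >= 95 % of cohorts
        rng = np.random.default_rng(1)
        n_rep = 100
        hits = 0
        for _ in range(n_rep):
            groups = {
                "control": rng.normal(0.9, 0.1, 10),
                "blocked": np.zeros(5),
            }
            res = between_group_test(groups)
            if res.adjusted_p_vs_control["blocked"] < 0.05:
                hits += 1
        assert hits >= 95

    def test_adjustment_only_vs_control(self):
        rng = np.random.default_rng(2)
        groups = {
            "control": rng.normal(0.9, 0.1, 10),
            "a": rng.normal(0.5, 0.1, 10),
            "b": rng.normal(0.9, 0.1, 10),
        }
        res = between_group_test(groups)
        assert set(res.adjusted_p_vs_control) == {"a", "b"}
        for label in ("a", "b"):
            assert res.adjusted_p_vs_control[label] >= res.raw_p_vs_control[label]


class TestBaselineEffectCorrelation:
    def test_proportional_effect(self):
        base = np.array([0.1, 0.15, 0.2, 0.25])
        r, p = baseline_effect_correlation(base, 2.0 * base)
        assert r == pytest.approx(1.0)

    def test_independent_null_small_r(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0.17, 0.03, 500)
        ratio = rng.normal(0.6, 0.1, 500)
        r, p = baseline_effect_correlation(base, ratio)
        assert abs(r) < 0.15

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            r, p = baseline_effect_correlation(
                rng.normal(0, 1, 15), rng.normal(0, 1, 15)
            )
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.7

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            baseline_effect_correlation([1.0, 2.0], [1.0, 2.0])


class TestResponderRate:
    def test_half_responders(self):
        effects = make_effects(10, 0.5)
        for i, eff in enumerate(effects):
            eff.responder = i < 5
        assert responder_rate(effects) == 0.5

    def test_full_block_group_all_respond(self):
        assert responder_rate(make_effects(5, 0.0, full_block=True)) == 1.0

    def test_no_responders(self):
        assert responder_rate(make_effects(5, 1.0, washout=1.0)) <= 0.4  # weak effect
        effects = make_effects(5, 1.0)
        for eff in effects:
            eff.responder = False
        assert responder_rate(effects) == 0.0

    def test_order_invariance(self):
        effects = make_effects(8, 0.5)
        assert responder_rate(effects) == responder_rate(effects[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            responder_rate([])


class TestAggregation:
    def test_means_match_direct_recomputation(self):
        effects = make_effects(12, 0.6)
        g = aggregate_group(effects)
        direct = np.mean(
            [e.phase_summaries["baseline"].sle_frequency_per_min for e in effects]
        )
        assert g.mean_sd["sle_frequency_per_min"]["baseline"][0] == pytest.approx(direct)
        assert g.mean_frequency_ratio == pytest.approx(
            np.mean([e.frequency_ratio for e in effects])
        )
        assert 0.0 <= g.responder_rate <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([])


class TestBuildReport:
    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_report([], {}, tmp_path)

    def test_control_only(self, tmp_path):
        effects = make_effects(5, 0.9)
        g = aggregate_group(effects)
        written = build_report([g], {"test": effects}, tmp_path)
        for path in written.values():
            assert len(open(path, "rb").read()) > 0

    def test_one_row_per_group(self, tmp_path):
        import pandas as pd

        groups = {}
        results = []
        for label, ratio in [("control", 0.9), ("a", 0.5), ("b", 0.0)]:
            effects = make_effects(4, ratio)
            for eff in effects:
                eff.group_label = label
            groups[label] = effects
            results.append(aggregate_group(effects))
        written = build_report(results, groups, tmp_path)
        table = pd.read_csv(written["summary_csv"])
        assert len(table) == 3
        assert set(table["group"]) == {"control", "a", "b"}
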
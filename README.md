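# fourap

Analysis pipeline for 4-aminopyridine (4-AP) induced seizure-like events
(SLEs) in combined hippocampal–entorhinal cortex slices, with a matched
synthetic data generator.  The package covers the three measurement layers
of this experiment type and ties them together into a reproducible
end-to-end run:

- **`fourap.synthetic_data`** — paired LFP traces and intrinsic-optical
  (IOS) image stacks with exact ground truth, parameterized per
  experimental arm (control plus lacosamide / zonisamide / levetiracetam
  at three doses each, using the published group means).
- **`fourap.lfp_events`** — drift correction and SLE detection using the
  three electrographic criteria (negative field-potential shift ≥ 0.5 mV,
  duration ≥ 10 s, superimposed ripple-like discharges), the 45-min slice
  inclusion rule, and per-phase summaries over the last 3–5 events.
- **`fourap.ios_analysis`** — ΔT/T normalization against a 20-frame
  control image, 20×20-pixel ROI time courses, the 1 % / >9-consecutive-
  frame pixel-involvement rule, per-region SLE areas, onset-region calls
  and pseudo-color rendering.
- **`fourap.pharm_stats`** — intervention/baseline effect ratios,
  responder rates (≥ 50 % frequency reduction), repeated-measures
  mixed-model comparisons with a paired-t fallback for full blocks,
  between-group ANOVA with Benjamini–Yekutieli-adjusted t-tests vs
  control, and baseline-vs-effect Pearson correlations.
- **`fourap.pipeline_cli`** — YAML-configured orchestration
  (simulate → detect → ios → stats → report) with a run manifest,
  exclusion bookkeeping and byte-identical outputs for a fixed seed.

## Command line

```bash
# simulate a cohort (traces as HDF5, masks + ground truth as JSON)
fourap simulate --group LAC_33 --n-slices 5 --seed 1 --out out/sim --with-ios

# detect SLEs in one trace
fourap detect --trace out/sim/LAC_33_s00.h5 --out out/events

# quantify one optical stack
fourap ios --stack out/sim/LAC_33_s00_sle00.tif --masks out/sim/masks.json \
    --threshold 1.0 --persistence 10 --out out/ios

# full pipeline, then stand-alone stats/report on its outputs
fourap run --seed 1 --groups control,LAC_33,LAC_100 --out out/run
fourap stats --cohort out/run --out out/stats
fourap report --stats out/stats/stats.json --out out/report
```

Exit codes: `0` success, `2` configuration/validation error, `1` runtime
failure.  All thresholds (0.5 mV, 10 s, 45 min, 20 control frames, 20×20
ROI, 1 % ΔT/T, 10 frames, α = 0.05, 50 % responder cut) live in
`PipelineConfig` and can be overridden from YAML.

## Layout

```
src/fourap/
  synthetic_data/   group specs, region masks, LFP + IOS generators, cohorts
  lfp_events.py     trace types, drift removal, SLE detector, phase summaries
  ios_analysis.py   ΔT/T, ROI, involvement, areas, onset region, rendering
  pharm_stats.py    slice effects, responder rate, within/between-group tests
  pipeline_cli/     config, orchestration, click CLI
  acceptance.py     parameter-recovery experiments
  io.py             HDF5/CSV traces, TIFF stacks, JSON masks & ground truth
tests/              pytest suite incl. oracles and acceptance criteria
scripts/acceptance.py
```
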
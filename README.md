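# bulbswitch

Analysis of task-dependent modulation in olfactory-bulb output neurons during
rapid task switching, from two-photon calcium imaging — plus a synthetic
cohort generator with full ground truth for validating every stage.

## The problem

Head-fixed mice alternate within a session between **fine** odour
discrimination (rewarded mixture α = 40/60 A+B vs unrewarded α′ = 60/40) and
**coarse** discrimination (α vs a distinct odour pair β), in three epochs:
Fine1 → Coarse → Fine2.  Because the rewarded odour α and its reward
association are identical in both tasks, any change in the α response isolates
the effect of task *demand*.  Mitral/tufted cells are imaged with GCaMP6f at
~30 Hz; the question is whether, how fast, and how selectively their odour
responses change with the task.

## What the package computes

Responses are ΔF/F = (F − F₀)/F₀ with a per-trial 2-s pre-odour baseline F₀;
the response amplitude *a* is the mean ΔF/F over the 1-s odour window, and a
response is significant when |a| > 3·σ̂ of the same window-mean statistic in
the pre-odour baseline.  On top of that currency:

- **Selectivity** — per ROI, a pooled-variance two-sample t-score comparing α
  vs α′ amplitudes during fine discrimination; the selectivity index is
  s = |t|, with t > 0 meaning α-preferring.
- **Task modulation** — per ROI, a two-tailed two-sample t on α amplitudes,
  fine vs coarse epochs (Fine2 truncated so both fine epochs contribute
  equally; probe trials excluded), with a label-permutation **shuffle
  control** calibrating the chance count and a **sniff control** that
  residualizes amplitudes on respiration features (rate, first-inhalation
  latency, inhalation count) before re-testing.
- **Population structure** — pseudo-population PCA trajectories per
  (odour, task) condition; Pearson correlation between the per-ROI mean α and
  α′ response vectors with the ROI-removal statistic
  Δr = (r_removed − r_full)/r_full against size-matched random removals; and
  cross-validated linear-discriminant decoding of S+ vs S− (shared shrunk
  covariance, stratified 2/3–1/3 splits).
- **Behaviour** — go/no-go scoring (lick in 1–2.5 s after odour onset on S+,
  no lick on S−) and switch-aligned accuracy curves.

The generator (`synthgen`) produces cohorts with the same trial grammar
(run length ≤ 3, ≥ 4 rewarded trials per epoch, ~1.6 rewarded-α′ probe trials
per session), GCaMP6f-like double-exponential transients whose odour-window
mean equals the ROI's true amplitude exactly, sniff-coupled and intrinsic
trial-to-trial variability, and a ground-truth labelled modulated
subpopulation (~12% of ROIs, drawn from the α-selective class, +0.17 ΔF/F on
α during fine epochs).

## Worked example

```python
import numpy as np
import bulbswitch as bw

cohort = bw.generate_cohort(bw.GeneratorConfig(), seed=1)        # 5 mice, 353 ROIs
equalized = [bw.equalize_fine_epochs(s) for s, _ in cohort]
tables = [bw.compute_responses(s) for s in equalized]
mods = [bw.task_modulation_test(t, alpha_level=0.05) for t in tables]
calib = bw.shuffle_control(tables, n_shuffles=50, seed=2)

called = np.concatenate([m.modulated for m in mods])
print(called.sum(), calib.mean_count)
```

Running `examples/03_selectivity_and_modulation.py` (which extends the above)
prints:

```
task-modulated ROIs: 59/353 called (47 truly modulated; sensitivity 0.98, FPR 0.042)
shuffle control: 18.1/353 flagged on average (nominal 5% -> 17.7)
sniff-residualized variant: 63/353 flagged
selectivity enrichment among modulated ROIs: KS = 0.74, p = 4.7e-27
```

Reading: 59 of 353 ROIs change their α response with task, far above the
~18 expected by chance (the shuffle control); the sniff control flags
slightly more, so respiration does not explain the modulation; and modulated
ROIs are strongly enriched for stimulus selectivity.
`examples/04_population_analysis.py` shows the population consequences:

```
trajectory separation in PC1-3 over the odour second:
  alpha fine1 vs coarse: 1.22
  alpha fine2 vs coarse: 1.45
  alpha fine1 vs fine2 : 0.41
alpha/alphaprime correlation change after ROI removal (mean over 5 animals):
  modulated ROIs removed: +15.7%
  size-matched random   : +0.03%
linear-discriminant decoding (% correct, mean over animals):
  fine  : all ROIs 100.0%   modulated removed  82.3%
  coarse: all ROIs 100.0%   modulated removed 100.0%
```

i.e. the α trajectory during coarse discrimination lies away from both fine
epochs (which superimpose), removing the modulated ROIs collapses the α/α′
decorrelation, and decoding degrades specifically for the fine task.

There is also a thin CLI (`bulbswitch synth|validate|score|analyse|report`)
and a one-call `bw.run_pipeline(bw.RunConfig(...))` that writes a full result
bundle plus a markdown report (see `examples/05_full_pipeline.py`).

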
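# Methods

This note documents the models, estimators and numerical conventions the
package implements, the assumptions behind the synthetic-data generator, and
the design choices made where the design was genuinely open.

## Data model and conventions

A session is a trial table, an ROI × frame fluorescence matrix and a
respiration trace on a common ~30 Hz frame clock.  Time is in seconds; odour
(valve) onset defines t = 0 within a trial; frames are indexed from 0; all
windows are half-open `[start, end)`, realized as the frames whose sample
times fall inside the interval.  The response window starts at valve opening
as recorded — the olfactometer's ~400 ms mixing constant is not compensated,
so "odour window" means the first second after valve opening.  Epochs run
Fine1 → Coarse → Fine2; `task` is `fine` for the two outer epochs and
`coarse` for the middle one.  Probe trials are rewarded α′ presentations and
occur only in the Coarse epoch.

On disk a session is a directory of `trials.csv` (human-readable trial
table; lick times semicolon-joined), `traces.h5` (float64 datasets `traces`
and `sniff`, written without HDF5 timestamps so serialization is
byte-deterministic) and `meta.yaml`.  The round trip is lossless.

## Response quantification

**ΔF/F.** F₀ is the mean raw fluorescence over the 2 s immediately preceding
each odour onset (per ROI, per trial).  The window length is a design choice:
it fits comfortably inside the 20-s inter-trial interval after the previous
transient has decayed, and averages 60 frames so F₀ estimation noise is small
relative to single-frame noise.  A per-session F₀ (mean of the per-trial
baselines) is available via `per_session_baseline=True`; the per-trial
variant is the default because it is robust to slow drift and bleaching.

**Amplitude.** The response amplitude is the arithmetic mean of ΔF/F over the
1-s odour window (30 frames at 30 Hz).  Trials whose window would run past
the end of the recording are dropped with a warning, never imputed.

**Significance.** A response is significant when |a| strictly exceeds 3× the
standard deviation of the *window-mean* statistic under the null.  Comparing
a 30-frame mean against a single-frame sd would misstate the null scale by
√30, so the null sd is estimated from pseudo-amplitudes built with the same
geometry as the real statistic — a 1-s window at [−1, 0) s against a 2-s
baseline at [−3, −1) s before each onset — whose sd across trials includes
both the window-mean noise and the F₀-estimation term.  With this
construction the false-positive rate of the 3-sd rule on response-free data
matches the two-sided Gaussian tail beyond 3 sd (≈0.27%), which the test
suite verifies against a Monte-Carlo oracle.  With fewer than two trials the
sd is undefined (NaN) and flagging raises.

**Epoch equalization.** To balance slow within-session effects, Fine2 is
truncated from its end so that both fine epochs contribute the same number
of trials.  When Fine2 is already the shorter epoch both are kept whole with
a warning — truncating Fine1 would discard the pre-switch reference period.
Retained trial records are never altered.

## Per-ROI statistics

**Selectivity.** For each ROI the fine-epoch α and α′ amplitudes are compared
with a pooled-variance, two-tailed two-sample t-test; t > 0 means
α-preferring and the selectivity index is s = |t|.  The t-statistic (rather
than a z-score) is appropriate at the 10–25 trials per odour available here.

**Task modulation.** Per ROI, a two-tailed pooled-variance two-sample t
compares α-trial amplitudes between the fine pool (Fine1 + equalized Fine2)
and the coarse pool; probe trials never enter either pool.  The significance
level defaults to 0.05 two-tailed, consistent with a chance rate near 5% in
the shuffle control.  The **shuffle control** permutes which of a session's
S+ α trials carry the fine label (group sizes preserved; one permutation per
session per shuffle, since ROIs of a session share trials) and re-runs the
test, reporting the per-shuffle flagged counts and their mean.

**Sniff control.** Respiration features per trial over the odour window:
inhalation rate (onsets per second), first-inhalation latency (NaN when no
onset falls in the window) and onset count.  Inhalation onsets are
negative-going zero crossings of the mean-subtracted flow trace (polarity
configurable), refined to sub-frame precision by linear interpolation —
without interpolation the ±1-frame quantization decorrelates window counts
from the true sniff timing and the regression loses most of its power.
Amplitudes of all S+ α trials, pooled across tasks, are regressed per ROI on
the features plus an intercept (one shared design matrix per session);
residuals replace the amplitudes and the task test is re-run
(`variant="sniff_residualized"`).  With a fixed window, rate and count are
exactly proportional; the rank check drops the redundant column with a
warning, which is the expected path rather than an anomaly.  NaN latencies
are mean-imputed so the per-ROI trial count never changes.  Pooling across
tasks is the default (a within-task fit is a config choice away): pooling
lets the regression absorb any sniff-task covariation, which is exactly the
confound the control is meant to exclude.

**Switch-aligned time-course.** For a chosen ROI set, each α-trial amplitude
minus that ROI's Fine1 α mean, averaged across ROIs at each α-trial index
relative to the two switches.  The first-coarse-trial change is tested with
a one-sample t across ROIs against zero; the recovery index is the first
Fine2 α-trial index at which an unpaired two-sample t (per-ROI amplitudes at
that index vs the pooled Fine1 amplitudes) is no longer significant.  In the
generator, modulation follows the epoch instantaneously, so the recovery
index is 0 by construction; on real data it reflects the adaptation time.

## Population analyses

**Pseudo-population and PCA.** Per ROI, the trial-averaged ΔF/F transient
over a peri-odour window (default [−1, 3) s) per condition, concatenated
across conditions and stacked over all sessions.  The default condition set
is (α:fine1, α:fine2, α′:fine, α:coarse): keeping the two fine epochs
separate is what lets the reversibility claim — fine trajectories
superimpose while the coarse trajectory departs — be read off directly.
Principal components treat each time-condition column as an observation in
ROI space: each ROI is centred on its mean over all columns, no variance
scaling (units stay ΔF/F); the transpose convention is a config switch on
the input matrix.  Component signs are fixed by making each component's
largest-|loading| positive.  Trajectory separations are mean Euclidean
distances in PC1–3, compared over the odour second — outside stimulation all
trajectories sit at the trial-averaging noise floor and distances carry no
signal.

**Correlation and ROI removal.** Per group (animal by default; per imaging
location/session via config), the per-ROI mean fine-epoch α and α′
amplitudes form two vectors; their Pearson r with and without a removal set
gives Δr = (r_removed − r_full)/r_full, reported in percent, with an
empty removal set defined as exactly 0.  Size-matched random removals
(default 100 replicates) provide the control distribution.

**Decoding.** Per session, trials of one task are represented by their
population amplitude vectors and classified S+ vs S− with a linear
discriminant: equal priors, one covariance shared across classes and shrunk
toward its diagonal with the analytic Ledoit–Wolf weight, because the ROI
count can exceed the trial count and the pooled sample covariance is then
singular.  Accuracy is the mean over 100 stratified 2/3 train / 1/3 test
splits (seeded); probe trials are excluded because their odour/reward
pairing is deliberately reversed.

**Enrichment.** Selectivity indices of modulated vs non-modulated ROIs are
compared with a two-sample Kolmogorov–Smirnov test, alongside the modulated
fraction among significantly selective ROIs vs the overall modulated
fraction.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes and
attaches exact ground truth; its defaults are the study conditions (5
animals / 353 ROIs, epochs of 15–25 trials, 1-s odour, 20-s ITI, probe count
Poisson with mean 1.6 truncated to leave at least two plain α S+ trials in
the Coarse epoch, ~12% modulated ROIs, +0.17 ΔF/F fine-task amplification of
α responses, ~30 Hz frames).

*Trial grammar.*  S+/S− per epoch are fair coin flips rejection-sampled
until no type runs longer than 3 and at least 4 S+ are present; infeasible
epoch lengths (< 5 trials) raise rather than silently relaxing a constraint.

*Tuning.*  Each ROI draws a selectivity class (defaults: 25% α-selective,
20% α′-selective), a base amplitude (uniform 0.05–0.5 ΔF/F on both
mixtures), a selectivity gap (uniform 0.01–0.10 ΔF/F added to the preferred
mixture) and an independent β amplitude.  The small gaps encode that a 40/60
vs 60/40 mixture pair drives most cells almost identically; they guarantee a
nonzero noiseless t-score sign for every selective ROI.  Modulated ROIs are
drawn inside the α-selective class at a conditional rate chosen so the
marginal modulated fraction equals `frac_modulated`; their α amplitude gains
`modulation_delta` during fine epochs only.

*Transients.*  Each trial adds a difference-of-exponentials kernel
(rise 0.05 s, decay 0.5 s — GCaMP6f-like; only the window mean matters
downstream) normalized on the frame grid so the mean over the odour window
equals the trial amplitude exactly; onsets snap to the frame grid, making
noiseless amplitude recovery exact to < 1e-9.  The amplitude itself is
tuning + task modulation + sniff coupling × (trial sniff rate − mean rate) +
intrinsic trial-to-trial jitter (sd 0.08 ΔF/F), and the trace adds i.i.d.
Gaussian frame noise (sd 0.1 ΔF/F).  The intrinsic jitter term models the
substantial trial-to-trial variability of awake calcium responses; without
it every amplitude statistic would be implausibly noise-free.

*Respiration.*  A quasi-periodic flow trace with per-cycle rate jitter
(mean 4 Hz, sd 0.5 Hz) whose exact onset times are ground truth; the trial
sniff rate that couples into amplitudes is the onset count in the odour
window, i.e. a quantity the analysis can recover exactly, which is what
makes the sniff confound linearly removable — the property the regression
control relies on.

*Behaviour.*  A Bernoulli agent: each trial is correct with probability
1 − lapse_rate (default 0.05); licks are placed inside the response window.
No reaction-time model.

*Determinism.*  Identical (config, seed) pairs yield bit-identical cohorts;
per-animal streams are spawned from the master seed via `SeedSequence`, so
animals are statistically independent but jointly reproducible.

What the generator does **not** model — and hence what passing tests do not
show about real data: neuropil/out-of-focus contamination, correlated
network noise beyond the common sniff term, adaptation dynamics at task
switches (modulation is a step function of epoch), reaction times and lick
microstructure, bleaching or slow drift, and any nonlinearity between
spiking and the fluorescence amplitude.

## Problem sizes and tolerances

Analyses in the examples, tests and acceptance script run at the study
scale: 353-ROI / 5-animal cohorts, 50 permutation seeds for shuffle
calibration, 500 sessions for the probe-count mean, 20 independent cohorts
for the decorrelation direction, 25–100 decoder splits.  Oracle-equivalence
checks (t, Pearson r, KS, PCA eigenstructure, LDA predictions, removal
change) are asserted to 1e-8 or tighter; noiseless construction identities
to 1e-9; stochastic calibrations to binomial sampling bands.  Degenerate
inputs fail loudly: non-positive F₀, infeasible trial grammars, missing
epochs, empty ROI sets and undefined correlations all raise with the
offending field named, and flat respiration traces yield absent features
rather than fabricated ones.

## Known limitations

The behavioural agent's accuracy does not dip after switches, so the
switch-aligned behaviour curve is only exercised for its bookkeeping, not
its shape.  The decoder's reported accuracies on synthetic data saturate
near 100% with all ROIs present; the informative quantity is the drop after
removing the modulated set.  The shuffle control's chance count is slightly
above α·n when true modulation is present (permuting a genuinely bimodal
sample inflates the two-sample t's rejection rate a little) — the same
effect is expected in the real procedure.  Window means discard all
within-window dynamics by design.
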
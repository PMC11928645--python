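# Methods

This note documents the statistical procedures the package implements, the
assumptions behind the synthetic-session generator, and the choices made
where the underlying procedure admits more than one reasonable reading.

## Task and data model

A session consists of trials of two types. In *pre-cue* trials a ring cue
(200 ms) marks the only location (top, middle, or bottom) where a color
change can occur; after a 500 ms delay, three colored squares appear for
400 ms (sample), vanish for 1100 ms (memory delay), and reappear for 400 ms
(compare), after which the subject reports "change" (peck at a stimulus
location) or "no change" (peck at center). *No-cue* trials replace cue +
delay with a single 700 ms delay, so sample onset is time-locked 700 ms
after initiation in both trial types — an invariant asserted on every
generated trial table. Each location shows one of two session-specific
colors; color identity is therefore reduced to an index {1, 2} per location.
Conditions (trial type × cue location × change/no-change × colors) are
balanced to within one trial, and the cue location never repeats more than
twice in a row among pre-cue trials.

Trial time is measured from ITI onset (the 2 s inter-trial interval precedes
initiation), so ITI spikes have non-negative timestamps and the ITI-rate
inclusion criterion can be evaluated from the same spike table.

## Synthetic sessions

Units are epoch-wise homogeneous Poisson processes (no refractory period, no
latency jitter — the simplest model satisfying the analyses' assumptions).
A unit's rate in an epoch is

    baseline × location_gain(attended) × Π_loc color_gain(loc, color_loc)^e_loc

with exponent `e_loc = attn_gain` at the trial's attended location and 1
elsewhere; location gains apply from cue onset through the compare phase,
color gains while colors are visible or memorized. Attention is all-or-none:
the attended location is the cued location in pre-cue trials and the agent's
internal choice in no-cue trials (a `fixed` agent always attends one
location; a `switching` agent re-draws uniformly with a per-block hazard —
hazard 1 with block length 1 gives the uniformly-attending null agent).
Outcomes are Bernoulli: a change at the attended location is hit with
`p_hit_attended` (default 0.9), elsewhere with `p_hit_unattended` (0.05);
no-change trials are correctly rejected with `p_cr` (0.95). These defaults
emulate the single-location strategy regime: near-ceiling detection at the
attended location, near-floor elsewhere, high correct rejections. Hits are
reported at the change location, false alarms at the attended location,
everything else at center (the residual error model is a modeling choice;
only hit/CR structure matters downstream).

Default tuning: tuned units carry a ×2 gain at a preferred location and/or a
1.5 : 1/1.5 color-gain contrast at a preferred location, with preferred
locations assigned round-robin so no location dominates the population code;
baselines are uniform on 4–12 Hz and the default attentional gain exponent
is 2. Aborted (gaze-break) trials are not simulated, because the analyses
exclude them globally.

What a green test does **not** establish: real recordings have
non-Poisson count statistics, rate drift, correlated noise across units, and
genuinely simultaneous trials; the generator has none of these. The
pseudo-population construction deliberately destroys cross-unit noise
correlations in real data too, so the decoding pathway is the closest match,
while absolute PEV magnitudes in the simulator should not be read as
predictions for tissue.

One interaction worth knowing when designing recovery experiments: units
whose *location* tuning is keyed to the attended location add firing-rate
variance in conditions where attention varies trial-to-trial (no-cue, or
cue-elsewhere). That alone depresses color PEV in those conditions, so a
population of jointly tuned units shows a positive information "gain" even
with `attn_gain = 1`. The attention-null recovery test therefore uses
color-only units, for which `attn_gain = 1` makes the three cue conditions
exactly exchangeable.

## Binning and inclusion rules

Firing rates are counted in half-open bins `[t, t + width)` (default 200 ms)
advanced in 20 ms steps, anchored at the analysis window start; a boundary
spike belongs to exactly one non-overlapping bin. The default window runs
from cue onset to choice onset (−0.7 s to +1.9 s around sample onset). Bin
timestamps are bin centers: with 200 ms bins any rate change is smeared by
±100 ms, which is why effects can appear to precede the event that causes
them. Whenever consecutive bins enter one test, every 10th bin is selected
so the tested bins are disjoint.

Units must average ≥ 0.5 spikes/s during the ITI of completed trials;
conditions need ≥ 20 completed trials. To equalize sample sizes across
conditions, analyses use the first 20 completed trials of each condition in
chronological session order (the only order the data define).

## Effect sizes and permutation nulls

Information is the one-way ANOVA effect size expressed as percent explained
variance, either from the sums of squares (ω²) or from the F statistic
(partial ω²); for one-way designs the two are algebraically identical, which
the suite checks to 1e-8 on 1000 random datasets. ω² can be negative for
weak effects; negative values are retained in all statistics. Only the
display transform clamps: for plotting, values are split by sign and
|v| < 1e-6 is floored at 1e-6 before taking log10.

The null distribution per unit-bin comes from recomputing ω² after shuffling
the trial labels (1000 shuffles; one shared shuffle per iteration across
units, since a shuffle severs the trial–label pairing for all units at
once). A bin is significant when the observed value exceeds the 95th
percentile of its shuffles; the [2.5, 97.5] band is exposed separately for
plotting. Under a simulated null the criterion's empirical false-positive
rate is 5% within Monte-Carlo tolerance (acceptance-tested).

Unit classification tests each factor per non-overlapping bin and applies
Bonferroni across **all** bin × factor tests within a unit (the color factor
is tested once per location, using that location's color index on all
pre-cue trials). The resulting categories — location-only, color-only,
both, none — partition the population.

## Attentional shift

For each location, the color-PEV time course is computed in three cue
conditions (cue at the location, no cue, cue elsewhere), with trial counts
equalized by the first-20 rule per color within each condition; gain and
loss are per-unit differences of these curves, averaged over the three
locations. "Overall" shift is (gain + loss)/2 per unit-bin, and the
population-level quantity is the absolute value of its across-unit mean —
chosen so the overall curve is the average of the gain and loss panels.
Per-bin significance uses the one-sample Wilcoxon signed-rank test across
units with Bonferroni correction over the tested bins. A Bayesian
signed-rank variant reported alongside the frequentist test in some
workflows is out of scope; only the frequentist test is implemented.

## Decoding

Pseudo-trials are assembled per condition by drawing, independently for each
unit, one of that unit's real trials of that condition (with replacement
when a unit has fewer real trials than pseudo-trials are requested;
without-replacement mode is available). Defaults: 40 pseudo-trials per cue
location, 120 total. Rates are z-scored per bin against the mean and SD
pooled over units × pseudo-trials (a per-unit variant sits behind a flag,
since "population-level" normalization admits both readings);
zero-variance bins are left at zero and flagged.

The classifier is a linear SVM with one-vs-one multi-class reduction
(recorded in output metadata; the classifier is a pluggable factory). Per
resample a stratified 90/10 split is drawn — 108 training and 12 test
pseudo-trials at the defaults; training happens per bin and testing in every
bin (temporal generalization). The shuffled baseline repeats the identical
pipeline with labels permuted per resample. Diagonal cells are significant
when the observed inner-95% interval lies wholly above the null's (at least
p < 0.025); off-diagonal cells are flagged when the observed mean exceeds
the null 95th percentile and survive only in 4-connected clusters of more
than five bins (1-D adjacency applies to diagonal-only analyses).
Resampling redraws only the train/test split by default; redrawing the
pseudo-trial assembly is the caller's choice by rebuilding the set.
Cross-temporal symmetry is *not* assumed or asserted anywhere.

Transfer decoding fits the same classifier on pre-cue pseudo-trials
(location-significant units only) and classifies unlabeled no-cue
pseudo-trials bin by bin (same time bin on both sides). Per bin, a χ²
goodness-of-fit test compares classification counts against the uniform
N/3 expectation, Bonferroni-corrected over bins; the trial-period summary is
the unweighted mean of per-bin fractions. Because each no-cue pseudo-trial
blends units drawn from different real trials, small imbalances in how often
the agent attended each location are amplified by the classifier's
winner-take-all behavior; unbiased chance-level classification for a
uniformly switching agent emerges when pooling across sessions, which is how
the recovery test is designed.

## Behavioral preference

Hit rate is hits/(hits+misses) per location (per cue location in pre-cue
trials, per change location in no-cue trials); correct rejection rate is
CRs/(CRs+FAs), pooled over locations in no-cue trials. Undefined rates
(zero denominators) are NaN, never zero.

The preference surrogate splits each session's completed trials into five
contiguous equal blocks and ranks locations by within-block no-cue hit rate;
undefined rates rank last, and all ties are broken by display order (top
before middle before bottom). The session's preferred location is the one
most often ranked first; dataset-level preference is the fraction of all
blocks of all sessions won by each location, recomputed for block counts
s = 3…10, with stability defined as an unchanged modal location across the
sweep (reported, not enforced). The surrogate has no trial-by-trial
resolution: sessions without a clear majority attended location are not
expected to be resolved, and the tests condition on a ≥ 60% majority.
Omnibus location effects across sessions use Kruskal–Wallis with Dunn-type
rank post hocs under Bonferroni control (hand-implemented; no suitable
post-hoc package is available in the environment).

## Numerical and degenerate-input conventions

- Zero within-group variance: F is +inf (p = 0) when group means differ,
  0 (p = 1) when they do not; ω² evaluates via sums of squares (giving 1 in
  the first case). Zero total variance raises a degenerate-value error.
- All-zero shift vectors: signed-rank p = 1 with a degeneracy flag.
- Identical data in every group of the omnibus test: p = 1 with a flag.
- All randomness flows from named seeds; a master seed spawns independent
  substreams for trials, agent, and spikes so stages can be reproduced
  independently. Pipeline outputs are byte-deterministic given a config.

## Known limitations

- Epoch-homogeneous Poisson rates: no within-epoch dynamics, adaptation, or
  latency; PSTH shapes are step functions smoothed only by binning.
- The agent has no learning, no reaction times, and no gaze breaks.
- The color factor uses session color indices, so cross-session color
  identity is meaningless by construction.
- Scaled-down defaults in tests (fewer resamples/permutations than the
  full-scale 1000) trade Monte-Carlo precision for runtime; the full-scale
  settings are the package defaults.
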
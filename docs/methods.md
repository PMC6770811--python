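# Methods

## Analysis conventions

All times are seconds. Epoch membership is half-open,
`[onset, onset + duration)`, so a spike at an epoch boundary is counted
exactly once when epochs tile a recording. Firing rate is the spike count
in the epoch divided by its duration.

**Net evoked activity.** Stimulus-epoch rate minus the rate in the window
`[onset − W, onset)`, with `W = background_window_s` defaulting to 120 s and
constrained to [60, 180] s — the conventional "mean of the 1–3 min preceding
the stimulus". The result may be negative (net inhibition). The analysis
errors out, naming the stimulus, if the window does not fit inside the
recording; the cohort generator always leaves ≥ 120 s of unstimulated time
before each stimulus and ≥ 180 s between stimuli.

**Burst detection.** A burst begins at a spike whose preceding silent
period is ≥ `min_silent_s` (default 100 ms) and whose next ISI is
≤ `max_intra_isi_s` (default 10 ms). The criterion as usually stated fixes
only the first two spikes; we extend the burst over every subsequent spike
while ISIs remain ≤ `max_intra_isi_s` (the common Spike2-style convention)
and count bursts as events, not spikes. For the first spike of a record (or
of a sliced scoring epoch) the observed gap from `t_start` counts as
silence; unobserved pre-recording time does not. Burst frequency is
reported in bursts/min.

**Joint-ISI map.** One entry per spike that has both a preceding interval
and a subsequent ISI; the entry is flagged as a burst start iff
`isi1 ≥ min_silent_s` and `isi2 ≤ max_intra_isi_s` (the dashed rectangle of
a joint-ISI plot). By default the first entry uses the observed
pre-first-spike silence as its preceding interval, so flagged entries
correspond one-to-one with detected bursts — an exact cross-check the test
suite exercises. That leading entry is a map convenience only; CV2 uses
true adjacent ISI pairs exclusively.

**CV2.** `CV2 = 2·|ISI₂ − ISI₁| / (ISI₂ + ISI₁)` per adjacent ISI pair,
with the absolute value taken. The signed variant averages to ~0 for any
process with exchangeable adjacent ISIs and therefore cannot express
"values ≥ 1 mean irregular firing"; the absolute form is bounded in [0, 2],
is exactly 0 for clock-like trains, and has expectation exactly 1 for
i.i.d. exponential ISIs (ISI₁/(ISI₁+ISI₂) is then uniform, so
E[CV2] = 2·E|1 − 2U| = 1). A per-neuron mean CV2 needs ≥ 2 ISI pairs in the
scoring epoch; neurons below that yield a missing value and are excluded
listwise from CV2 group tests, with the exclusion logged.

**Per-neuron summaries.** Background rate, burst rate and mean CV2 are
computed on the condition's background epoch (the train sliced to the
epoch, so the epoch start defines observable silence); net evoked rates on
each stimulus epoch. All metrics are invariant to translating the whole
recording in time, and CV2 to rescaling time.

## Statistical tests

The sampling unit is the neuron (one neuron per animal is assumed upstream;
neurons are treated as independent). All p-values are two-tailed and
α = 0.05.

- *Paired t* (two drug conditions): t = mean(d)/(sd(d)/√n), df = n − 1.
  Zero-variance differences are flagged degenerate: t = 0, p = 1 when all
  differences are zero, |t| = ∞, p = 0 otherwise.
- *One-way between-group ANOVA*: F with df (k−1, N−k) from the standard
  between/within sums-of-squares partition; post hocs are pooled-variance
  two-sample t-tests over all k(k−1)/2 pairs, Bonferroni-corrected
  (p·m capped at 1).
- *Repeated-measures ANOVA* (three drug conditions): the within-subject
  partition SS_total = SS_conditions + SS_subjects + SS_error, F with df
  (k−1, (k−1)(n−1)); post hocs are Bonferroni-corrected paired t-tests.
  **No sphericity correction is applied** — the analysis deliberately
  reports uncorrected degrees of freedom (e.g. (2, 8) for n = 5, k = 3),
  matching field practice for this battery; with k = 3 and small n the
  liberality is modest but real, and is a documented limitation.

The sums-of-squares code is authored here (it is the analysis's core
contract); scipy supplies only the t and F distributions. The test suite
cross-checks against scipy.stats (paired t, one-way F) and pingouin
(repeated-measures F) as independent oracles.

## Synthetic cohort generator

The generator is a statistical stand-in for the firing phenotypes the
analysis is meant to separate — it makes no biophysical claims.

**Tonic process.** ISIs are `refractory_s + Gamma(shape, scale)`. The
15 ms absolute refractory period (default) is physiological and guarantees
tonic ISIs exceed the 10 ms intra-burst criterion, so detected bursts are
exactly the injected ones. `gamma_shape` steers regularity: 1 is
Poisson-like (mean CV2 ≈ 0.95 at 2 Hz with the refractory period), 3 is
moderately regular (≈ 0.65 including burst-pair contributions), 100 is
clock-like (< 0.2). Each simulated interval starts with a 5-mean-ISI
warm-up that is discarded, so the process is near equilibrium at interval
onset.

**Burst process.** Burst events arrive at Poisson rate
`burst_rate_per_min`; each carries `2 + (Geometric − 1)` spikes (mean
`burst_size`, default 3) with i.i.d. intra-burst ISIs uniform on
[0.4, 1.0]·`intra_burst_isi_s` (default 6 ms). Tonic spikes are carved out
of a 105 ms window before each burst onset — enforcing the detector's
silent-period condition — and a 20 ms guard after the last burst spike;
bursts whose windows would collide are thinned. The thinning and
end-cropping lose ≈ 1% of bursts at 3–4 bursts/min, a bias well inside the
Monte-Carlo error of the recovery checks.

**Rate calibration.** `bg_rate_hz` is the *total* expected background
rate. With burst rate λ_b (s⁻¹), mean burst size m, and carved window
length w, the tonic renewal rate is set to
`(bg_rate_hz − λ_b·m) / (1 − λ_b·w)`, so burst spikes and silent-gap
carving cancel in expectation and the analyzed background rate estimates
the generative value directly (verified to |bias| < 3 MC SE over 200
seeds). Infeasible combinations (burst spikes exceeding the target rate,
silent gaps covering most of the record, tonic rate at or beyond the
refractory limit) raise errors.

**Epoch layout.** Each condition segment is 720 s: background epoch
[0, 300), a 15 s innocuous stimulus at 420 s, a 15 s noxious stimulus at
630 s — ≥ 120 s of unstimulated time before each stimulus and 195 s between
them. Stimuli multiply all rates by `evoked_gain_innoc`/`evoked_gain_nox`
for their span (a stationary multiplier; no adaptation, since the analysis
uses epoch totals only). Drug conditions append further segments with all
rates multiplied by a per-condition factor (instantaneous; dialysis
kinetics are out of scope). The canonical protocols are
`antagonist_only` (predrug, drug), `agonist_then_antagonist` (predrug,
agonist, agonist+antagonist — the reversal restores baseline), and
`antagonist_then_agonist` (predrug, antagonist, antagonist+agonist — the
inhibition persists).

**Default phenotypes.** Sham: 2 Hz background, gains 1.5×/2.5×,
2 bursts/min, gamma shape 3. Neuropathic (SNL): double background
(4 Hz) and burst rate (4/min), raised gains (2.0×/3.5×), shape 1
(Poisson-like, CV2 ≈ 0.9). Knockdown: sham phenotype. The default cohort
is 18 sham / 10 SNL / 6 knockdown neurons.

**Between-neuron heterogeneity.** Within a group, each neuron's background
rate is jittered by a mean-preserving lognormal factor with σ = 0.25, and
its burst rate with σ = 0.15. These spreads were fixed at design time by a
power analysis: they are large enough to dominate within-neuron counting
noise (realistic cohort scatter, SE bars comparable to published group
summaries) while keeping the injected doubled contrasts detectable by
Bonferroni post hocs in ≳ 90% of cohorts at the 18/10/6 group sizes. Burst
propensity gets the smaller spread because a 5-min background epoch already
contributes substantial Poisson counting noise to a per-neuron burst rate.
CV2 is not jittered between neurons; its group contrasts are driven by the
shape parameter alone.

**RNG discipline.** Each neuron draws from its own Philox stream keyed by
(cohort seed, group index, neuron index), so adding neurons or groups never
changes any other neuron's spikes, and cohort files are byte-reproducible
from the seed.

## Numerical choices

- Timestamps serialize as 6-decimal fixed-point text (sub-ms precision,
  ample for the 10 ms criterion); write→read→write is byte-identical.
- Duplicate or non-monotone timestamps are rejected at parse time with the
  offending line number — duplicates would corrupt every ISI statistic.
- Recording span defaults to first/last spike when no metadata sidecar
  exists (slightly inflating rates on sparse trains; the generator always
  writes sidecars).
- Coincident spikes produced by merging processes are deduplicated at a
  1e-7 s tolerance before validation.
- Degenerate statistics (zero variance) return flagged results rather than
  NaNs or exceptions, as described above.

## Problem sizes used by the checks

The verification battery simulates at desk scale, chosen so the whole
suite runs in well under a minute of simulation time: burst-detector oracle
equivalence on 1000 random boundary-heavy trains plus an exhaustive sweep
of all 837 trains of 2–6 spikes on a criterion-straddling grid; CV2
analytics on a Poisson train with > 10⁵ ISI pairs; type-I calibration with
10 000 null replicates per test at cohort-realistic n (8 pairs; 18/10/6
groups; 5 × 3 within-subject); parameter recovery over 200 seeds of 5-min
backgrounds; and cohort contrast power / null calibration over 100
simulated cohorts each.

## What passing tests do and do not show

The generator produces stationary renewal-plus-burst activity with
log-normal between-neuron spread. Real recordings add non-stationarity
(drift, state changes), rate adaptation within stimuli, spike-sorting
contamination, correlated noise across simultaneously recorded units, and
heavier-tailed rate distributions. Passing the recovery and power checks
shows the estimators and tests behave correctly under the stated model at
the stated sample sizes — not that any particular biological effect size
will be detected in real data. The repeated-measures ANOVA's lack of
sphericity correction and the treatment of neurons as independent samples
are inherited, documented assumptions of the analysis design.
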
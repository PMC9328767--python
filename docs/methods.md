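# Methods

This note documents the statistical models the package implements, the
synthetic-data conditions used to validate them, and the numerical and design
choices made where the procedures left room.

## Signal model and ISC estimators

All ISC machinery assumes a signal-plus-noise model: subject *i* in a group
observes `x_i(t) = s(t) + ε_i(t)`, with `s` the group's shared
stimulus-driven signal and `ε_i` independent noise. If the signal has unit
variance and the noise variance is σ², every subject pair shares correlation
`r = 1/(1+σ²)` per feature (equicorrelation). Under that model:

- split-half ISC with half size `m = n/2` has expectation
  `shISC = m·r/(1+(m−1)·r)` (each half-mean has variance `1 + σ²/m` and the
  halves covary through the signal only);
- leave-one-out ISC has expectation `looISC = r·√((n−1)/(1+(n−2)·r))`;
- `expected_pw_from_sh` inverts the first identity
  (`r = sh/(m−(m−1)·sh)`, undefined when `sh ≥ m/(m−1)`, which is rejected)
  and `expected_loo_from_sh` composes it with the second.

These are expectation-level identities: applying the conversion to one noisy
`shISC` draw yields a noisy estimate, unbiased in the Monte-Carlo sense (the
validation battery measures the bias directly; it is ~3×10⁻⁴ at n=40,
T=750, 50 replicates).

Correlations are computed per feature on the raw timecourses and averaged as
plain `r` (no Fisher-z) across a parcel's features and across splits. For
pre-averaged parcel timecourses (one feature per parcel) the feature average
is a no-op. Constant timecourses yield missing values, never silent zeros.

### Between-group ISC

Two groups with mean signals `s_A`, `s_B` correlated at ρ_b: each group is
split into halves; the within-group term is the correlation of the two
half-means, the between-group term the mean of the four cross-group
half-mean correlations, and

    ISC_b = between / √(within_A · within_B).

Both terms carry the same attenuation factor `v/(v+σ²/m)` (signal variance
over half-mean variance), which cancels in the ratio — so ISC_b estimates
ρ_b itself rather than a noise-shrunk version. Averaging all four cross
correlations (rather than one) keeps the statistic symmetric in the groups
and reduces split noise; the within/between terms are averaged across a
parcel's features *before* the ratio, because per-feature ratios are
unstable when a within term is near zero. When either within-group term is
≤ 0 the statistic is undefined and reported missing. Inference is
lower-tailed: permuted (mixed-age) groups share one population signal, so
the null concentrates near 1 and a genuinely different pair of groups falls
*below* it.

The split-half seed can be given per group; each subsample draw uses an
independently derived split seed.

## Ordered-event HMM

A parcel's group-average timecourse (z-scored per feature over time) is
modeled as a left-to-right chain over K events: the state starts pinned at
event 1, ends pinned at event K, and at each TR either stays or advances by
one. The advance probability is `p = (K−1)/(T−1)` — the value under which
the chain is expected to traverse its K events in T steps. Emissions are
isotropic Gaussians around the event's spatial pattern with a single shared
variance; log-likelihoods are normalized per timepoint per feature so that
model-fit differences are comparable across parcels (and so the 0.002
structure threshold has a fixed meaning).

**Fitting.** The E-step is an exact forward–backward pass in log space over
the two-banded transition structure (log-probabilities clipped at −700
before exponentiation); the M-step sets each pattern to its γ-weighted data
mean and the variance to the γ-weighted mean squared residual per feature.
EM stops when the relative log-likelihood change falls below 1e-4 (cap 100
iterations, best iterate kept); the training log-likelihood is
non-decreasing across iterations up to numerical slack.

**Initialization.** EM on this model is sensitive to its starting point:
with naive equal-block initial patterns it reliably merges short events and
splits long ones, even on noiseless data, and variance-annealing schedules
do not escape that basin. Patterns are therefore initialized from the
*globally optimal* contiguous K-segmentation of the timecourse — the
hard-assignment maximum-likelihood segmentation under the shared-variance
Gaussian model — computed exactly by dynamic programming on within-segment
sums of squares (O(K·T²) with cumulative sums). From that basin, exact EM
refines the soft posterior. With this initializer, noiseless recovery is
exact and noisy recovery at the validation settings (K=7, V=50, T=300,
average-level noise σ=0.5) places 100% of boundaries within ±2 TRs.

**Event-count selection.** Five-fold cross-validation over subjects: per
fold, fit on the z-scored average of the training subjects for every K in
the grid — the unique integers of a 15-point geometric sequence from 2 to
50: {2,3,4,5,6,8,10,13,16,20,25,32,40,50} — and score the held-out average
under frozen patterns and variance (forward pass conditioned on ending in
event K). The selected K is the mean over folds of the per-fold argmax,
rounded to the nearest grid value when a single integer is needed for joint
fitting. The structure index is the best cross-validated log-likelihood over
the grid minus that of the two-event baseline; parcels below 0.002 (on the
normalized scale) in both groups are screened out as lacking event
structure. Since the grid contains K=2, the index is non-negative and sits
at exactly 0 for structureless noise.

A property of this CV scheme worth knowing: the held-out average (1/5 of
subjects) carries ~5× the noise variance of the training average (4/5), so
the frozen training variance is optimistic for the test data, and the
mismatch penalizes sharp (high-K) models more than smooth ones. With
moderate per-subject noise this biases the selected K downward (e.g. true
K=8, n=10: σ=1.0 selects ≈5, σ=0.25 selects ≈6, σ≤0.15 selects 8 exactly).
The event-count recovery validation therefore runs at per-subject σ=0.1 — a
strongly structured group — while boundary recovery at known K, which has no
such train/test asymmetry, is validated at σ=0.5.

**Joint fitting.** One model is fit to two groups simultaneously: E-steps
run separately on each group's average (each group has its own γ and hence
its own event timing), while the M-step pools sufficient statistics so
patterns and variance are shared. Per CV fold the joint model is trained on
the two training averages and evaluated on the two held-out averages; the
reported γ per group is the fold-average of held-out posteriors, and
held-out log-likelihoods are fold-averaged per group.

## Event timing

The anticipation score of a posterior γ is `Σ_t Σ_k k·γ(t,k)` — bounded by
[T, K·T]; since the expected event index is monotone in t, a group whose
transitions occur earlier has pointwise larger expected indices and hence a
larger score. Group differences of this score are tested by permutation
(below). The boundary timecourse of a γ is the first difference of the
expected event index (leading zero, clipped at 0 against numerical noise);
its sum telescopes to at most K−1.

Cross-correlation lags between boundary timecourses are computed at every
integer TR lag within ±30 TRs (24 s, covering the tens-of-seconds effects
the anticipation analyses target) on truncated, unpadded overlaps; a
parabola through the integer peak and its two neighbors gives the sub-TR
vertex `ℓ + (r₋−r₊)/(2(r₋−2r₀+r₊))`, returned in seconds. **Sign
convention: positive lag means the first argument (the brain timecourse)
leads the second (behavior).** A peak at the lag-range boundary is returned
as-is with a warning; collinear triples return the integer peak.

## Behavioral boundaries and ROI responses

Rater boundary times are binned at `floor(time/TR)` (stimulus-end times to
the last TR), counted across raters, and convolved (full mode, truncated to
T) with the gamma HRF `h(t) = (t/(p·q))^p · e^{p−t/q}`, p=8.6, q=0.547 s,
sampled on the TR grid over 25 s — unit peak at t = p·q ≈ 4.70 s. Raters
whose median inter-boundary interval (measuring segments from the stimulus
start) is under 1 s are dropped as spam clickers; raters with no boundaries
at all are retained, since the criterion is undefined for them and they
contribute nothing downstream. Consensus boundaries: on a 1 s grid, the
fraction of raters with an annotation within ±2 s is computed; maximal runs
exceeding 50% agreement are merged, each contributing one boundary at its
agreement-weighted center. The grid step, window and agreement level are
exposed as parameters; only the >50% rule is fixed by the procedure being
reconstructed.

ROI timecourses are correlated with the boundary regressor at integer-TR
delays from 0 to 10 s (ROI delayed relative to boundaries, truncated
overlap); no detrending is applied since Pearson correlation is
location/scale invariant. Age effects on any per-subject quantity
(boundary correlation, ROI volume) are ordinary Pearson tests with
t-distributed p-values on n−2 df.

## Permutation inference and FDR

Group comparisons are tested by permuting group labels across subjects
within gender strata, so every permuted group retains its original gender
composition; one permuted labeling (identified by its seed) is reused across
all subsamples of one permutation index. The schedule is adaptive: 100
permutations first; if any parcel's exceedance proportion is below α=0.05,
batches of 1000 are added until every parcel has at least one exceedance or
6000 have been run; a parcel still at zero exceedances then has the observed
value appended to its own null, so p ≥ 1/(N+1). Sidedness is registered per
statistic: ISC_b lower tail; ISC-magnitude, model-fit and timing differences
two-sided via absolute value. Undefined observed statistics (missing ISC_b)
propagate as missing p-values; undefined null draws count as exceedances,
which is conservative. Behavioral (rater-split) analyses use a fixed
10,000-permutation plan. FDR across parcels is Benjamini–Hochberg at q=0.05
(statsmodels step-up behind the module surface, verified exactly against a
brute-force implementation of the definition).

HMM-based permutation statistics follow a frozen-model rule: per CV fold the
joint model is trained once on the true-label training data, and each
permutation only re-evaluates label-shuffled held-out subjects at the
already-selected K. Labels are shuffled within each fold's held-out set
(preserving group counts) rather than through one global subject
permutation — this keeps both groups represented in every fold under every
permutation and is exchangeable under the null; it is a reconstruction where
the procedure's published description leaves the fold bookkeeping open.

## Synthetic data: what it emulates and what it does not

The generator produces the structures the analyses assume, with known
truth: K z-scored spatial patterns per parcel; a piecewise-constant group-A
signal over specified boundary TRs; a group-B signal built from the same
patterns at boundaries shifted `shift_tr` TRs earlier and then mixed with an
independent unit-variance process to correlation ρ_b; per-subject white
Gaussian noise; uniform ages within each group's range and exact gender
counts; rater annotations with Gaussian jitter, Bernoulli misses and
clipping; and ROI timecourses whose boundary-locked gain varies linearly
with age. Defaults mirror the acquisition geometry the pipeline targets
(TR = 0.8 s, 750 TRs, 40 subjects and 22 males per group, ages 5–8 vs
16–19) with noise σ=2 so the within-group pairwise correlation is 0.2 — a
realistic naturalistic-viewing ISC level.

Deliberately absent: hemodynamic convolution of the neural signal (off so
HMM recovery checks stay exact against integer-TR truth), temporally
autocorrelated or physiological noise, head motion, vertex-level spatial
structure, and uneven age distributions. Passing tests therefore establish
correctness of the estimators and procedures under their own model
assumptions — parameter recovery, calibration, ordering — not robustness to
real fMRI artifacts.

## Validation battery problem sizes

`scripts/acceptance.py` (and the mirrored tests) use: 50 replicate cohorts
for ISC_b recovery and conversion agreement (n=40/group, T=750); 20 seeds
for boundary recovery (K=7, V=50, T=300, average-level σ=0.5, 10 subjects),
event-count recovery (σ=0.1) and the noise structure screen (V=25); 20
replicates for anticipation detection (5-TR lead, 10 subjects/group, a
100→+200→500 adaptive plan — detection at p<0.05 needs only ~1/300
p-resolution, while the library default keeps the full 100→+1000→6000
schedule); 10 replicates of n=400 subjects for the age-effect band with 200
null runs for the false-positive rate; 500 runs for permutation-level
calibration and 1000 random vectors for the FDR oracle. On one CPU the
whole battery completes in under two minutes.

## Known limitations

- The equicorrelated conversions assume homogeneous subjects; systematic
  subgroup structure within a group biases `expected_*_from_sh` relative to
  the direct estimators.
- The shared emission variance makes the HMM favor segmentations with
  homogeneous within-event variance; per-event variances are out of scope.
- CV event-count selection inherits the train/test noise asymmetry described
  above; comparisons of K *between* groups of equal size are unaffected
  (both inherit the same bias), but absolute K estimates at high noise are
  conservative.
- The adaptive permutation p-value is computed as exceedances/N (with the
  observed value appended only at zero exceedances), matching the procedure
  it reconstructs; its finite-sample level is ≈α+1/N rather than exactly α,
  which the calibration checks bound empirically.
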
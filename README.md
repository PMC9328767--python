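# eventisc

Inter-subject correlation and ordered-event HMM analysis of naturalistic
fMRI timecourses, for researchers studying how groups (e.g. age cohorts)
differ in their shared processing of a movie or narrative stimulus.

The package consumes already-parcellated BOLD timecourses (one
`parcels × time` — or `parcels × features × time` — array per subject, with a
subject metadata table), plus optional behavioral event-boundary annotations
and ROI-average timecourses. It implements:

- **Within-group ISC.** Split-half ISC (`shISC`): correlate the mean
  timecourses of two random half-groups. Under an equicorrelated
  signal-plus-noise model with pairwise correlation *r* and half size
  *m = n/2*,

      shISC = m·r / (1 + (m−1)·r),
      looISC = r·√((n−1) / (1 + (n−2)·r)),

  so pairwise and leave-one-out ISC are recovered in expectation from one
  split (`expected_pw_from_sh`, `expected_loo_from_sh`); `loo_isc` also
  computes leave-one-out ISC directly.
- **Between-group ISC (`isc_b`).** The cross-group half-mean correlation
  divided by the geometric mean of the two within-group split-half
  correlations. The noise-attenuation factor cancels between numerator and
  denominator, making ISC_b a consistent estimator of the correlation ρ_b
  between the two groups' mean stimulus-driven signals.
- **Ordered-event HMM.** A left-to-right hidden Markov model whose states
  are stable spatial patterns traversed in fixed order (start pinned to
  event 1, end to event K, transitions stay-or-advance with per-step advance
  probability (K−1)/(T−1)), Gaussian emissions with one shared variance.
  Event counts are selected by five-fold cross-validation over subjects on a
  2–50 grid; a two-event-baseline structure index screens parcels without
  event structure. `joint_fit` shares patterns and variance across two
  groups while letting each group's event *timing* differ.
- **Event timing.** Anticipation scores (time-summed expected event index;
  the group that transitions earlier scores higher), group timing
  differences, and cross-correlation lags against behavioral boundary
  timecourses with sub-TR quadratic peak refinement.
- **Boundary responses.** Rater QC, >50%-agreement consensus boundaries, a
  gamma HRF regressor `h(t) = (t/(p·q))^p · e^(p−t/q)` (p = 8.6,
  q = 0.547 s, peak 4.70 s), lagged ROI–boundary correlations to 10 s, and
  Pearson age effects.
- **Inference.** Gender-matched subsampling, gender-stratified group-label
  permutation with an adaptive schedule (100 initial, +1000 batches, cap
  6000, observed value appended when no permutation exceeds it), and
  Benjamini–Hochberg FDR.

A synthetic-data generator (`eventisc.synth`) produces all of these inputs
with known ground truth and drives the test suite.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/05_anticipation.py` simulates two 10-subject groups whose
shared event structure is identical except that group B runs 5 TRs (4.0 s at
TR = 0.8 s) ahead of group A, jointly fits the event model, and prints:

```
anticipation score A: 1203.9
anticipation score B: 1233.9  (B leads, so B > A)
timing difference (B - A): 30.0, permutation p = 0.0020 (500 permutations)
cross-correlation lag (B vs A): 4.00 s (truth 4.00 s), r = 1.00
```

The anticipation score difference of 30 is the 5-TR lead accumulated over
the six event transitions; the permutation p-value comes from re-evaluating
the frozen joint model on label-shuffled held-out subjects; and the lag
between the two groups' boundary timecourses recovers the generating 4-second
shift exactly.

A thin CLI mirrors the pipeline (`eventisc simulate`, `eventisc run-all
--config config.yaml`, plus per-stage subcommands); all analysis logic lives
in the importable modules.

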
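"""Detect that one group's event transitions anticipate the other's.

Group B is generated 5 TRs (4.0 s) ahead of group A. A single HMM is jointly
fit to both groups (shared event patterns, group-specific timing); the
anticipation score — the time-summed expected event index of the posterior —
is larger for the leading group, and a gender-stratified label permutation
test gives its significance.
"""

import numpy as np

import eventisc as ev
from eventisc.inference import timing_difference_test
from eventisc.perm import PermutationPlan

spec = ev.SimSpec(
    n_parcels=1, n_features=50, n_timepoints=300, tr=0.8,
    n_subjects_per_group=10, n_male_per_group=5, noise_sd=1.0,
    rho_b=1.0, shift_tr=5,
    boundaries_tr=(35, 80, 120, 170, 215, 260), seed=4,
)
cohort, truth = ev.make_cohort(spec)
gs = cohort.groups()
subj_a = [s.pvt[0] for s in gs["A"].subjects]
subj_b = [s.pvt[0] for s in gs["B"].subjects]

fit = ev.joint_fit(subj_a, subj_b, 7, seed=0)
score_a = ev.anticipation_score(fit.gamma["A"])
score_b = ev.anticipation_score(fit.gamma["B"])
print(f"anticipation score A: {score_a:.1f}")
print(f"anticipation score B: {score_b:.1f}  (B leads, so B > A)")

res = timing_difference_test(
    subj_b, subj_a, 7,
    PermutationPlan(n_initial=100, increment=200, max_total=500, seed=0),
    seed=0,
)
print(f"timing difference (B - A): {float(np.atleast_1d(res.observed)[0]):.1f}, "
      f"permutation p = {res.p[0]:.4f} ({res.n_perms} permutations)")

lag_s, r = ev.xcorr_lag(
    ev.boundary_timecourse_from_gamma(fit.gamma["B"]),
    ev.boundary_timecourse_from_gamma(fit.gamma["A"]),
    max_lag_tr=30, tr=spec.tr,
)
print(f"cross-correlation lag (B vs A): {lag_s:.2f} s (truth 4.00 s), r = {r:.2f}")
print("positive lag = first argument leads; the quadratic fit around the")
print("integer peak refines the lag below the TR grid.")
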
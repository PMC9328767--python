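"""Between-group ISC: estimate the correlation between two groups' mean
stimulus-driven signals, corrected for within-group noise.

Raw cross-group correlations are attenuated by within-group noise; dividing
by the geometric mean of the within-group split-half correlations cancels the
attenuation, so ISC_b recovers the generating rho_b even though each half-mean
timecourse is noisy.
"""

import numpy as np

import eventisc as ev

rho_true = 0.6
vals, raw = [], []
for rep in range(20):
    spec = ev.SimSpec(
        n_parcels=1, n_features=1, n_timepoints=750, n_subjects_per_group=40,
        noise_sd=2.0, rho_b=rho_true,
        boundaries_tr=tuple(range(50, 750, 50)), seed=100 + rep,
    )
    cohort, _ = ev.make_cohort(spec)
    gs = cohort.groups()
    vals.append(ev.isc_b(gs["A"], gs["B"], seed=rep)[0])
    a = gs["A"].stack()[:, 0, 0, :].mean(axis=0)
    b = gs["B"].stack()[:, 0, 0, :].mean(axis=0)
    raw.append(np.corrcoef(a, b)[0, 1])

print(f"generating rho_b:                    {rho_true:.3f}")
print(f"raw full-group mean correlation:     {np.mean(raw):.3f}  (noise-attenuated)")
print(f"ISC_b over 20 replicate cohorts:     {np.nanmean(vals):.3f}")
print()
print("ISC_b removes the attenuation the raw between-group correlation keeps;")
print("a raw value below ISC_b reflects finite within-group consistency, not")
print("a real difference between the groups' mean responses.")
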
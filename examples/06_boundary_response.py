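"""Boundary-evoked ROI responses and their age effect.

Rater annotations are filtered (spam clickers removed), reduced to consensus
boundaries, and convolved with the gamma HRF into a regressor on the TR grid.
Simulated ROI timecourses whose boundary-locked gain falls with age then show
a negative correlation between age and the per-subject boundary correlation —
the signature of a boundary response that weakens over development.
"""

import numpy as np

import eventisc as ev
from eventisc._utils import pearson_lastaxis

true_b = np.arange(30.0, 570.0, 45.0)
ann = ev.make_annotations(true_b, n_raters=21, jitter_sd_s=1.0, miss_rate=0.2,
                          seed=0, duration_s=600.0)
ann = ev.filter_raters(ann)
consensus = ev.consensus_boundaries(ann)
print(f"raters kept after QC: {len(ann)}")
print(f"true boundaries (s):      {true_b.astype(int)}")
print(f"consensus boundaries (s): {np.round(consensus).astype(int)}")

T, tr = 750, 0.8
btc = ev.boundary_timecourse(ann, T, tr)
kernel = ev.hrf_kernel(tr)
print(f"\nHRF peak at {np.argmax(kernel) * tr:.1f} s (analytic maximum 4.70 s)")

rng = np.random.default_rng(1)
ages = rng.uniform(5, 19, 400)
roi = ev.make_boundary_locked_roi(ages, btc, base_gain=1.0,
                                  slope_per_year=-0.02, noise_sd=5.0, seed=2)
lag0 = pearson_lastaxis(roi, btc[None, :])
r, p = ev.age_effect(lag0, ages)
print(f"age vs boundary-correlation: r = {r:.3f}, p = {p:.2g}")
print("negative r: older subjects show weaker boundary-locked responses,")
print("matching the generating slope of -0.02 gain units per year.")
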
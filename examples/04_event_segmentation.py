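"""Segment a neural timecourse into ordered events and choose the event count.

Fits the left-to-right HMM to a group-average timecourse, recovers event
boundaries from the posterior, and selects the number of events by five-fold
cross-validation over subjects, with the two-event-baseline structure screen.
"""

import numpy as np

import eventisc as ev
from eventisc._utils import zscore

rng = np.random.default_rng(1)
true_K, V, T = 7, 50, 300
patterns = ev.make_event_patterns(true_K, V, seed=1)
true_b = np.array([35, 80, 120, 170, 215, 260])
signal = ev.make_group_signal(patterns, true_b, T)
subjects = ev.make_subjects(signal, 10, 0.5, seed=2)

avg = zscore(np.mean(subjects, axis=0), axis=-1)
model, gamma = ev.fit_hmm(avg, true_K)
rec = ev.recovered_boundaries(gamma)
print(f"true boundaries (TR):      {true_b}")
print(f"recovered boundaries (TR): {rec}")
print(f"training loglik/(T*V):     {model.train_loglik:.3f}")

low_noise = ev.make_subjects(signal, 10, 0.1, seed=3)
k_cv = ev.select_k(low_noise, seed=0)
idx = ev.event_structure_index(low_noise, seed=0)
print(f"\ncross-validated K:         {k_cv}  (true {true_K}; grid {ev.DEFAULT_K_GRID})")
print(f"event-structure index:     {idx:.4f}  (threshold {ev.DEFAULT_STRUCTURE_THRESHOLD})")

noise = [rng.standard_normal((25, T)) for _ in range(10)]
print(f"index on pure noise:       {ev.event_structure_index(noise, seed=0):.4f}"
      "  (no event structure)")
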
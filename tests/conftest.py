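"""Shared fixtures and oracles for the eventisc test suite.

All fixtures generate data programmatically with fixed seeds; nothing is
loaded from disk except where file round-trips are the thing under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import eventisc as ev
from eventisc import hmm as H
from eventisc._utils import zscore


def rand_bounds(rng: np.random.Generator, K: int, T: int, min_gap: int = 10) -> np.ndarray:
    """K-1 random strictly increasing event onsets with a minimum segment length."""
    while True:
        b = np.sort(rng.choice(np.arange(min_gap, T - min_gap), K - 1, replace=False))
        if np.all(np.diff(b) >= min_gap):
            return b


def brute_force_posterior(data, patterns, var, K):
    """Posterior event-membership and log-likelihood by explicit enumeration
    of every monotone state path (start in event 1, end in event K, advance
    by at most one per step). Independent oracle for the forward-backward
    recursion; feasible for T <= 12, K <= 3."""
    V, T = data.shape
    p = (K - 1) / (T - 1)
    logB = H._log_emissions(data, patterns, var)
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        if path[0] != 0 or path[-1] != K - 1:
            continue
        if any(not 0 <= b - a <= 1 for a, b in zip(path, path[1:])):
            continue
        lp = sum(logB[t, k] for t, k in enumerate(path))
        for a, b in zip(path, path[1:]):
            if b == a:
                lp += np.log(1 - p) if a < K - 1 else 0.0
            else:
                lp += np.log(p)
        w = np.exp(lp)
        total += w
        for t, k in enumerate(path):
            post[t, k] += w
    return post / total, float(np.log(total))


def structured_subjects(seed: int, K: int = 7, V: int = 50, T: int = 300,
                        n: int = 10, noise_sd: float = 0.5):
    """One group of event-structured subjects plus the true boundaries."""
    rng = np.random.default_rng(seed)
    pats = ev.make_event_patterns(K, V, seed=seed)
    b = rand_bounds(rng, K, T)
    sig = ev.make_group_signal(pats, b, T)
    subs = ev.make_subjects(sig, n, noise_sd, seed=seed + 1)
    return subs, b, pats


@pytest.fixture
def small_cohort():
    """Two-group cohort small enough for every estimator: 8 subjects/group,
    2 parcels, T=200, moderate noise, rho_b=0.8."""
    spec = ev.SimSpec(
        n_parcels=2, n_features=1, n_timepoints=200, n_subjects_per_group=8,
        n_male_per_group=4, noise_sd=1.0, rho_b=0.8,
        boundaries_tr=(40, 80, 120, 160), seed=42,
    )
    cohort, truth = ev.make_cohort(spec)
    return cohort, truth


@pytest.fixture
def clean_gamma():
    """Hard, noiseless posterior: K=3 events switching at t=4 and t=9, T=12."""
    g = np.zeros((12, 3))
    g[:4, 0] = 1.0
    g[4:9, 1] = 1.0
    g[9:, 2] = 1.0
    return g


@pytest.fixture
def annotations_12():
    """21 raters reproducing 12 true boundaries with jitter and misses."""
    true_b = np.arange(40.0, 600.0, 46.0)[:12]
    ann = ev.make_annotations(true_b, n_raters=21, jitter_sd_s=1.0,
                              miss_rate=0.2, seed=7, duration_s=600.0)
    return ann, true_b


def zscored_average(subjects) -> np.ndarray:
    return zscore(np.mean([np.asarray(s, float) for s in subjects], axis=0), axis=-1)


def brute_force_bh(p, q=0.05):
    """Step-up Benjamini-Hochberg by direct application of the definition;
    independent oracle for the FDR implementation."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    thresholds = q * np.arange(1, n + 1) / n
    below = np.nonzero(sorted_p <= thresholds)[0]
    k = below.max() + 1 if below.size else 0
    sig = np.zeros(n, dtype=bool)
    sig[order[:k]] = True
    qvals = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, sorted_p[i] * n / (i + 1))
        qvals[order[i]] = running
    return qvals, sig
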
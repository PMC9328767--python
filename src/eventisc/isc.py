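"""Inter-subject correlation estimators.

Three estimators of shared stimulus-driven response are supported:

* split-half ISC (``shISC``): correlate the mean timecourses of two random
  halves of the group;
* pairwise ISC (``pwISC``): average correlation over subject pairs;
* leave-one-out ISC (``looISC``): correlate each subject with the mean of the
  others.

Under an equicorrelated signal-plus-noise model (every pair of subjects shares
pairwise correlation r per feature) the three are interconvertible in
expectation: with half size m = n/2,

    shISC = m r / (1 + (m - 1) r)
    looISC = r sqrt((n - 1) / (1 + (n - 2) r))

``expected_pw_from_sh`` / ``expected_loo_from_sh`` invert and apply these
identities.

The between-group statistic ``isc_b`` estimates the correlation rho_b between
two groups' mean stimulus-driven signals: the cross-group half-mean
correlation divided by the geometric mean of the two within-group split-half
correlations. The attenuation factor (signal variance over half-mean variance)
appears identically in numerator and denominator and cancels, so ISC_b is a
consistent estimator of rho_b even at finite noise.

All correlations are computed per feature on the raw timecourses (Pearson r is
location/scale invariant) and then averaged across a parcel's features; plain
averaging of r, not Fisher-z.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._utils import child_seed, logger, pearson_lastaxis
from .datatypes import CohortDataset


def _halves(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random equal-half partition of n subject indices; odd n drops one."""
    idx = rng.permutation(n)
    if n % 2:
        logger.info("odd group size %d: dropping subject index %d", n, idx[-1])
        idx = idx[:-1]
    m = idx.size // 2
    return idx[:m], idx[m:]


def _half_means(stack: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    h1, h2 = _halves(stack.shape[0], rng)
    return stack[h1].mean(axis=0), stack[h2].mean(axis=0)


def _parcel_mean_r(r_pv: np.ndarray) -> np.ndarray:
    """Average per-feature correlations within each parcel, ignoring NaN
    features; a parcel with no valid feature stays NaN."""
    valid = ~np.isnan(r_pv)
    n_valid = valid.sum(axis=1)
    sums = np.where(valid, r_pv, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / n_valid
    return np.where(n_valid > 0, out, np.nan)


def split_half_isc(group: CohortDataset, seed: int) -> np.ndarray:
    """Per-parcel split-half ISC.

    Subjects are randomly partitioned into two equal halves; per feature, the
    two half-mean timecourses are correlated, then r is averaged across the
    parcel's features. Constant half-means yield NaN for that feature.
    """
    if len(group) < 4:
        raise ValueError("split_half_isc needs at least 4 subjects")
    m1, m2 = _half_means(group.stack(), np.random.default_rng(seed))
    r = pearson_lastaxis(m1, m2)  # (parcels, features)
    if np.isnan(r).any():
        logger.info("split_half_isc: %d constant feature(s) -> NaN", int(np.isnan(r).sum()))
    return _parcel_mean_r(r)


def expected_pw_from_sh(sh: float, n: int) -> float:
    """Expected pairwise ISC implied by a split-half ISC at group size n."""
    if n < 4 or n % 2:
        raise ValueError("n must be even and >= 4")
    m = n // 2
    den = m - (m - 1) * sh
    if den <= 0:
        raise ValueError(f"shISC={sh} inconsistent with half size m={m}")
    return sh / den


def expected_loo_from_sh(sh: float, n: int) -> float:
    """Expected leave-one-out ISC implied by a split-half ISC at group size n."""
    r = expected_pw_from_sh(sh, n)
    return r * np.sqrt((n - 1) / (1 + (n - 2) * r))


def loo_isc(group: CohortDataset) -> np.ndarray:
    """Leave-one-out ISC: (n_subjects, parcels) array of correlations between
    each subject and the mean of all others (feature-averaged per parcel)."""
    if len(group) < 3:
        raise ValueError("loo_isc needs at least 3 subjects")
    stack = group.stack()
    n = stack.shape[0]
    total = stack.sum(axis=0)
    out = np.empty((n, stack.shape[1]))
    for i in range(n):
        others = (total - stack[i]) / (n - 1)
        out[i] = _parcel_mean_r(pearson_lastaxis(stack[i], others))
    return out


def isc_b(group_a: CohortDataset, group_b: CohortDataset, seed) -> np.ndarray:
    """Per-parcel between-group ISC.

    Each group is split into halves. Within-group term: r between that group's
    two half-means. Between-group term: mean of the four cross-group half-mean
    correlations. ISC_b = between / sqrt(within_a * within_b). Parcels where
    either within-group term is <= 0 are returned as NaN (statistic undefined).

    ``seed`` is either an int (child split seeds derived per group) or an
    explicit ``(seed_a, seed_b)`` pair; with the pair swapped alongside the
    groups the statistic is exactly symmetric.
    """
    if len(group_a) < 4 or len(group_b) < 4:
        raise ValueError("isc_b needs at least 4 subjects per group")
    if isinstance(seed, (tuple, list)):
        seed_a, seed_b = seed
    else:
        seed_a, seed_b = child_seed(seed, 0), child_seed(seed, 1)
    a1, a2 = _half_means(group_a.stack(), np.random.default_rng(seed_a))
    b1, b2 = _half_means(group_b.stack(), np.random.default_rng(seed_b))

    within_a = _parcel_mean_r(pearson_lastaxis(a1, a2))
    within_b = _parcel_mean_r(pearson_lastaxis(b1, b2))
    between = np.mean(
        [
            _parcel_mean_r(pearson_lastaxis(x, y))
            for x in (a1, a2)
            for y in (b1, b2)
        ],
        axis=0,
    )
    bad = ~((within_a > 0) & (within_b > 0))
    if bad.any():
        logger.info("isc_b: %d parcel(s) with non-positive within-group term", int(bad.sum()))
    with np.errstate(invalid="ignore"):
        out = between / np.sqrt(within_a * within_b)
    out[bad] = np.nan
    return out


def covariate_vs_isc(loo_values, covariate) -> tuple[float, float]:
    """Pearson r (and two-sided t-test p, n-2 df) between per-subject looISC
    values and a nuisance covariate such as median framewise displacement."""
    loo_values = np.asarray(loo_values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if loo_values.shape != covariate.shape or loo_values.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.std(covariate) == 0:
        raise ValueError("zero-variance covariate")
    r, p = stats.pearsonr(loo_values, covariate)
    return float(r), float(p)


def subsample_average(
    statistic_fn,
    dataset: CohortDataset,
    n_subsamples: int = 5,
    seeds=None,
    subsample_fn=None,
):
    """Average a per-parcel statistic over random (typically gender-matched)
    subsamples of a dataset.

    ``statistic_fn(subcohort, seed)`` maps a subsampled cohort to a statistic;
    ``subsample_fn(dataset, seed)`` returns the subject ids of one draw (when
    None the full dataset is reused each draw). Returns ``(mean, per_draw)``.
    """
    if seeds is None:
        seeds = list(range(n_subsamples))
    if len(seeds) != n_subsamples:
        raise ValueError("need one seed per subsample")
    draws = []
    for s in seeds:
        sub = dataset if subsample_fn is None else dataset.select(subsample_fn(dataset, s))
        draws.append(np.asarray(statistic_fn(sub, s), dtype=float))
    per_draw = np.stack(draws)
    return per_draw.mean(axis=0), per_draw
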
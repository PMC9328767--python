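"""Ordered-event hidden Markov model for neural timecourse segmentation.

The model assumes a timecourse traverses K stable spatial activity patterns in
a fixed order: a left-to-right chain that starts pinned in event 1, ends
pinned in event K, and at each step either stays in the current event or
advances by one. Emissions are isotropic Gaussians around the event pattern,

    log p(x_t | k) = -||x_t - m_k||^2 / (2 sigma^2) - (V/2) log(2 pi sigma^2),

with a single shared variance. The per-step advance probability is
p = (K - 1) / (T - 1), the value under which K events are traversed in T
steps in expectation.

Fitting alternates a constrained forward-backward E-step (in log space) with
closed-form M-steps (gamma-weighted pattern means, gamma-weighted mean squared
residual per feature for the variance). Log-likelihoods are reported
normalized per timepoint per feature so that model-fit differences are
comparable across parcels and the event-structure screening threshold
(default 0.002) is meaningful.

Event counts are selected by k-fold cross-validation over subjects: train on
the average timecourse of the training subjects, score the held-out average,
and report the mean over folds of the per-fold argmax K. ``joint_fit`` shares
patterns and variance across two groups (pooled M-step) while letting each
group have its own event timing (separate E-steps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.model_selection import KFold

from ._utils import logger, zscore
from .datatypes import EventSegModel

# the unique integers of a 15-point geometric sequence from 2 to 50
DEFAULT_K_GRID = (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50)
DEFAULT_STRUCTURE_THRESHOLD = 0.002

_LOG_FLOOR = -700.0  # clip before exponentiation


def _check_data(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (features, time)")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite data")
    return data


def _log_emissions(data: np.ndarray, patterns: np.ndarray, var: float) -> np.ndarray:
    """(T, K) Gaussian log-emission matrix for (V, T) data."""
    V = data.shape[0]
    x = data.T  # (T, V)
    d2 = (
        (x**2).sum(axis=1)[:, None]
        - 2.0 * x @ patterns.T
        + (patterns**2).sum(axis=1)[None, :]
    )
    return -d2 / (2.0 * var) - 0.5 * V * np.log(2.0 * np.pi * var)


def _transition_logs(K: int, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-state log stay / log advance probabilities for the chain."""
    p = (K - 1) / (T - 1)
    log_stay = np.full(K, np.log1p(-p) if p < 1 else -np.inf)
    log_stay[-1] = 0.0  # final event is absorbing
    log_adv = np.full(K, np.log(p) if p > 0 else -np.inf)
    log_adv[-1] = -np.inf
    return log_stay, log_adv


@njit(cache=True)
def _logaddexp(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + np.log(np.exp(a - m) + np.exp(b - m))


@njit(cache=True)
def _forward(logB, log_stay, log_adv):
    T, K = logB.shape
    alpha = np.full((T, K), -np.inf)
    alpha[0, 0] = logB[0, 0]  # start pinned to event 1
    for t in range(1, T):
        for k in range(K):
            stay = alpha[t - 1, k] + log_stay[k]
            adv = alpha[t - 1, k - 1] + log_adv[k - 1] if k > 0 else -np.inf
            alpha[t, k] = _logaddexp(stay, adv) + logB[t, k]
    return alpha


@njit(cache=True)
def _backward(logB, log_stay, log_adv):
    T, K = logB.shape
    beta = np.full((T, K), -np.inf)
    beta[-1, -1] = 0.0  # end pinned to event K
    for t in range(T - 2, -1, -1):
        for k in range(K):
            stay = log_stay[k] + logB[t + 1, k] + beta[t + 1, k]
            adv = (
                log_adv[k] + logB[t + 1, k + 1] + beta[t + 1, k + 1]
                if k < K - 1
                else -np.inf
            )
            beta[t, k] = _logaddexp(stay, adv)
    return beta


def _posterior(logB: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    """Posterior event-membership matrix gamma (T, K) and the path
    log-likelihood, conditioned on starting in event 1 and ending in event K."""
    T = logB.shape[0]
    log_stay, log_adv = _transition_logs(K, T)
    alpha = _forward(logB, log_stay, log_adv)
    beta = _backward(logB, log_stay, log_adv)
    loglik = float(alpha[-1, -1])
    logg = alpha + beta - loglik
    gamma = np.exp(np.clip(logg, _LOG_FLOOR, 0.0))
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, loglik




def _dp_segmentation(data: np.ndarray, K: int) -> np.ndarray:
    """Optimal contiguous K-segmentation of (V, T) data minimizing total
    within-segment sum of squares (the hard-assignment ML segmentation under
    the shared-variance Gaussian model). Returns K-1 boundary indices.

    Dynamic programming over segment start points; cost of segment [a, b) is
    sum ||x_t||^2 - ||sum x_t||^2 / (b - a), all from cumulative sums.
    """
    V, T = data.shape
    x = data.T
    cv = np.vstack([np.zeros(V), np.cumsum(x, axis=0)])  # (T+1, V)
    c1 = np.concatenate([[0.0], np.cumsum((x**2).sum(axis=1))])
    s = (cv**2).sum(axis=1)
    # cost[a, b] for segment [a, b), b > a
    gram = cv @ cv.T
    lens = np.arange(T + 1)[None, :] - np.arange(T + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (c1[None, :] - c1[:, None]) - (
            s[None, :] - 2.0 * gram + s[:, None]
        ) / lens
    cost[lens <= 0] = np.inf

    D = cost[0].copy()  # D[b]: best cost of segmenting [0, b) into 1 segment
    back = np.zeros((K, T + 1), dtype=int)
    for k in range(1, K):
        M = D[:, None] + cost  # a -> b
        back[k] = np.argmin(M, axis=0)
        D = M[back[k], np.arange(T + 1)]
    bounds = []
    b = T
    for k in range(K - 1, 0, -1):
        b = int(back[k][b])
        bounds.append(b)
    return np.array(bounds[::-1])


def _init_patterns_dp(datas, K):
    """Event patterns from the DP segmentation of the across-group mean data
    (so multiple groups share a single initialization)."""
    mean_data = datas[0] if len(datas) == 1 else np.mean(datas, axis=0)
    edges = np.concatenate([[0], _dp_segmentation(mean_data, K), [mean_data.shape[1]]])
    return np.stack(
        [
            mean_data[:, edges[k] : max(edges[k + 1], edges[k] + 1)].mean(axis=1)
            for k in range(K)
        ]
    )


def _em(datas, K, max_iter, tol):
    """Exact EM over one or more groups sharing patterns and variance,
    initialized from the optimal hard K-segmentation.
    Returns ((mean normalized ll, patterns, var, per-group gammas), ll trace)."""
    V, T = datas[0].shape
    patterns = _init_patterns_dp(datas, K)
    var = 1.0
    trace = []
    best = None
    for _ in range(max_iter):
        gammas, lls = [], []
        for data in datas:
            gamma, ll = _posterior(_log_emissions(data, patterns, var), K)
            gammas.append(gamma)
            lls.append(ll)
        ll = float(np.mean(lls))
        trace.append(ll)
        if best is None or ll > best[0]:
            best = (ll, patterns, var, gammas)
        if len(trace) > 1 and abs(ll - trace[-2]) < tol * max(abs(trace[-2]), 1.0):
            break
        patterns, var = _m_step(datas, gammas, patterns)
    else:
        logger.warning("event HMM: no convergence in %d iterations (K=%d)", max_iter, K)
    return best, trace


def fit_hmm(
    avg_data: np.ndarray,
    K: int,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[EventSegModel, np.ndarray]:
    """Fit the ordered-event HMM to a (features, time) group-average
    timecourse (z-scored per feature). Returns the model and gamma (T, K)."""
    data = _check_data(avg_data)
    V, T = data.shape
    if not 2 <= K <= T:
        raise ValueError(f"need 2 <= K <= T, got K={K}, T={T}")
    (ll, patterns, var, gammas), _ = _em([data], K, max_iter, tol)
    model = EventSegModel(K=K, patterns=patterns, noise_var=var, train_loglik=ll / (T * V))
    return model, gammas[0]


def em_loglik_trace(avg_data: np.ndarray, K: int, max_iter: int = 100) -> np.ndarray:
    """Training log-likelihood across exact EM iterations (post warm-up);
    non-decreasing up to numerical slack."""
    data = _check_data(avg_data)
    _, trace = _em([data], K, max_iter, tol=0.0)
    return np.asarray(trace)


def _m_step(datas, gammas, old_patterns):
    """Pooled M-step over one or more (data, gamma) groups sharing patterns."""
    K = gammas[0].shape[1]
    V = datas[0].shape[0]
    num = np.zeros((K, V))
    wsum = np.zeros(K)
    for data, gamma in zip(datas, gammas):
        num += gamma.T @ data.T
        wsum += gamma.sum(axis=0)
    patterns = old_patterns.copy()
    ok = wsum > 1e-12
    patterns[ok] = num[ok] / wsum[ok, None]
    sq = 0.0
    tot = 0.0
    for data, gamma in zip(datas, gammas):
        d2 = (
            (data.T**2).sum(axis=1)[:, None]
            - 2.0 * data.T @ patterns.T
            + (patterns**2).sum(axis=1)[None, :]
        )
        sq += (gamma * d2).sum()
        tot += gamma.shape[0] * V
    var = max(sq / tot, 1e-12)
    return patterns, var


def held_out_loglik(model: EventSegModel, avg_data: np.ndarray) -> float:
    """Normalized (per timepoint per feature) log-likelihood of held-out
    group-average data under frozen patterns and variance, conditioned on
    ending in event K."""
    data = _check_data(avg_data)
    V, T = data.shape
    if data.shape[0] != model.patterns.shape[1]:
        raise ValueError("feature dimension mismatch with model patterns")
    logB = _log_emissions(data, model.patterns, model.noise_var)
    log_stay, log_adv = _transition_logs(model.K, T)
    alpha = _forward(logB, log_stay, log_adv)
    return float(alpha[-1, -1]) / (T * V)


def posterior(model: EventSegModel, avg_data: np.ndarray) -> np.ndarray:
    """Gamma (T, K) of held-out data under a frozen model."""
    data = _check_data(avg_data)
    logB = _log_emissions(data, model.patterns, model.noise_var)
    gamma, _ = _posterior(logB, model.K)
    return gamma


def recovered_boundaries(gamma: np.ndarray) -> np.ndarray:
    """Event-onset TRs from the argmax-gamma state path (transition points)."""
    path = np.argmax(gamma, axis=1)
    return np.flatnonzero(np.diff(path) > 0) + 1


def fold_indices(n_subjects: int, n_folds: int, seed: int):
    """Shuffled k-fold (train, test) index pairs over subjects."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n_subjects)))


def _fold_averages(subject_datas, n_folds: int, seed: int):
    """Per-fold (train_average, test_average) z-scored (V, T) pairs."""
    stack = np.stack([np.asarray(d, dtype=float) for d in subject_datas])
    out = []
    for train, test in fold_indices(stack.shape[0], n_folds, seed):
        out.append(
            (
                zscore(stack[train].mean(axis=0), axis=-1),
                zscore(stack[test].mean(axis=0), axis=-1),
            )
        )
    return out


def cv_loglik_curve(
    group_subjects, K_grid=DEFAULT_K_GRID, n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """(n_folds, len(K_grid)) held-out normalized log-likelihoods."""
    if len(group_subjects) < n_folds:
        raise ValueError("fewer subjects than folds")
    folds = _fold_averages(group_subjects, n_folds, seed)
    curve = np.empty((n_folds, len(K_grid)))
    for f, (train_avg, test_avg) in enumerate(folds):
        for j, K in enumerate(K_grid):
            model, _ = fit_hmm(train_avg, K)
            curve[f, j] = held_out_loglik(model, test_avg)
    return curve


def select_k(
    group_subjects, K_grid=DEFAULT_K_GRID, n_folds: int = 5, seed: int = 0
) -> float:
    """Cross-validated event count: mean over folds of the per-fold argmax K."""
    curve = cv_loglik_curve(group_subjects, K_grid, n_folds, seed)
    K_grid = np.asarray(K_grid)
    return float(K_grid[np.argmax(curve, axis=1)].mean())


def event_structure_index(
    group_subjects, K_grid=DEFAULT_K_GRID, n_folds: int = 5, seed: int = 0
) -> float:
    """Best cross-validated log-likelihood over the K grid minus that of the
    two-event baseline, on the normalized scale. Values below the screening
    threshold flag a parcel as lacking event structure."""
    K_grid = list(K_grid)
    if 2 not in K_grid:
        K_grid = [2] + K_grid
    curve = cv_loglik_curve(group_subjects, K_grid, n_folds, seed).mean(axis=0)
    return float(curve.max() - curve[K_grid.index(2)])


def snap_to_grid(K: float, K_grid=DEFAULT_K_GRID) -> int:
    """Round a (possibly fractional) cross-validated K to the nearest grid value."""
    K_grid = np.asarray(K_grid)
    return int(K_grid[np.argmin(np.abs(K_grid - K))])


@dataclass
class JointFitResult:
    model: EventSegModel
    gamma: dict[str, np.ndarray]  # group label -> fold-averaged held-out gamma
    heldout_loglik: dict[str, float]
    fold_models: list[EventSegModel]
    fold_test_averages: dict[str, list[np.ndarray]]


def _joint_em(datas, K, max_iter=100, tol=1e-4):
    """EM over multiple groups with shared patterns/variance, separate gammas."""
    V, T = datas[0].shape
    (ll, patterns, var, gammas), _ = _em(datas, K, max_iter, tol)
    model = EventSegModel(K=K, patterns=patterns, noise_var=var, train_loglik=ll / (T * V))
    return model, gammas


def joint_fit(
    group_a_subjects,
    group_b_subjects,
    K: int,
    n_folds: int = 5,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> JointFitResult:
    """Jointly fit one ordered-event HMM to two groups.

    Both groups share event patterns and emission variance (pooled M-step);
    each group's event timing is free (separate E-step on its own training
    average). Per fold, the joint model is trained on the two training
    averages and evaluated on the two held-out averages; the returned gamma
    per group is the average of the held-out posteriors across folds, and the
    returned model is the joint fit to the full group averages.
    """
    la, lb = labels
    if len(group_a_subjects) < n_folds or len(group_b_subjects) < n_folds:
        raise ValueError("fewer subjects than folds in a group")
    folds_a = _fold_averages(group_a_subjects, n_folds, seed)
    folds_b = _fold_averages(group_b_subjects, n_folds, seed)

    gam = {la: [], lb: []}
    ho_ll = {la: [], lb: []}
    fold_models = []
    fold_tests = {la: [], lb: []}
    for (tr_a, te_a), (tr_b, te_b) in zip(folds_a, folds_b):
        model, _ = _joint_em([tr_a, tr_b], K)
        fold_models.append(model)
        for lab, te in ((la, te_a), (lb, te_b)):
            gam[lab].append(posterior(model, te))
            ho_ll[lab].append(held_out_loglik(model, te))
            fold_tests[lab].append(te)

    full_a = zscore(np.mean([np.asarray(d, float) for d in group_a_subjects], axis=0), axis=-1)
    full_b = zscore(np.mean([np.asarray(d, float) for d in group_b_subjects], axis=0), axis=-1)
    full_model, _ = _joint_em([full_a, full_b], K)
    return JointFitResult(
        model=full_model,
        gamma={lab: np.mean(g, axis=0) for lab, g in gam.items()},
        heldout_loglik={lab: float(np.mean(v)) for lab, v in ho_ll.items()},
        fold_models=fold_models,
        fold_test_averages=fold_tests,
    )


def select_k_joint(
    group_a_subjects,
    group_b_subjects,
    K_grid=DEFAULT_K_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> int:
    """K maximizing the across-group mean cross-validated held-out
    log-likelihood of the jointly fit model."""
    folds_a = _fold_averages(group_a_subjects, n_folds, seed)
    folds_b = _fold_averages(group_b_subjects, n_folds, seed)
    scores = []
    for K in K_grid:
        vals = []
        for (tr_a, te_a), (tr_b, te_b) in zip(folds_a, folds_b):
            model, _ = _joint_em([tr_a, tr_b], K)
            vals.append(0.5 * (held_out_loglik(model, te_a) + held_out_loglik(model, te_b)))
        scores.append(np.mean(vals))
    return int(np.asarray(K_grid)[int(np.argmax(scores))])


def boundary_timecourse_from_gamma(gamma: np.ndarray) -> np.ndarray:
    """Derivative of the expected event index over time (leading 0 pad).

    For the left-to-right chain the expected event index is monotone
    non-decreasing, so the derivative is non-negative; tiny negative values
    from numerical noise are clipped to 0.
    """
    gamma = np.asarray(gamma, dtype=float)
    expected = gamma @ np.arange(1, gamma.shape[1] + 1)
    out = np.concatenate([[0.0], np.diff(expected)])
    return np.clip(out, 0.0, None)
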
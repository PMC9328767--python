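"""Event-timing statistics: anticipation scores, group timing differences,
and lag estimation against behavioral boundary timecourses.

The anticipation score of a posterior event-membership matrix gamma is
sum_t sum_k k * gamma(t, k) — the time-summed expected event index. A group
whose event transitions occur earlier spends more time in later events and so
has the larger score; the score is bounded by [T, K*T].

Lag sign convention (configurable nowhere, documented everywhere): positive
lag means the FIRST argument (the brain boundary timecourse) LEADS the second
(the behavioral timecourse), i.e. brain transitions occur earlier in time.
"""

from __future__ import annotations

import numpy as np

from ._utils import logger, pearson_lastaxis
from .hmm import boundary_timecourse_from_gamma


def anticipation_score(gamma: np.ndarray) -> float:
    """Sum over time of the expected (1-based) event index."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2:
        raise ValueError("gamma must be (T, K)")
    return float((gamma @ np.arange(1, gamma.shape[1] + 1)).sum())


def group_timing_difference(gamma_a: np.ndarray, gamma_b: np.ndarray) -> float:
    """anticipation_score(gamma_a) - anticipation_score(gamma_b); positive
    means group A's event transitions lead group B's."""
    gamma_a = np.asarray(gamma_a)
    gamma_b = np.asarray(gamma_b)
    if gamma_a.shape != gamma_b.shape:
        raise ValueError("gamma matrices must share (T, K) shape")
    return anticipation_score(gamma_a) - anticipation_score(gamma_b)


def _quadratic_vertex(r_minus: float, r_0: float, r_plus: float) -> float:
    """Vertex offset (in lag steps, relative to the center point) of the
    parabola through three equally spaced correlations."""
    denom = r_minus - 2.0 * r_0 + r_plus
    if denom == 0:  # collinear: keep the integer peak
        return 0.0
    return 0.5 * (r_minus - r_plus) / denom


def xcorr_lag(
    brain_boundary_tc: np.ndarray,
    behav_boundary_tc: np.ndarray,
    max_lag_tr: int,
    tr: float,
) -> tuple[float, float]:
    """Cross-correlation lag between a brain-derived and a behavioral boundary
    timecourse, with sub-TR refinement.

    Pearson r is computed at every integer TR lag in [-max_lag_tr, +max_lag_tr]
    on the overlapping (truncated, unpadded) segments; a parabola through the
    integer peak and its two neighbors gives the vertex lag, returned in
    seconds with positive = brain leads behavior. A peak at the range boundary
    is returned as-is with a warning (no interpolation possible).
    Returns ``(lag_seconds, r_at_integer_peak)``.
    """
    x = np.asarray(brain_boundary_tc, dtype=float)
    y = np.asarray(behav_boundary_tc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need equal-length 1-D timecourses")
    max_lag_tr = int(max_lag_tr)
    if max_lag_tr < 1 or max_lag_tr >= x.size - 1:
        raise ValueError("max_lag_tr must be in [1, T-2]")
    lags = np.arange(-max_lag_tr, max_lag_tr + 1)
    rs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        # positive lag: brain leads -> brain[t] aligns with behavior[t + lag]
        if lag >= 0:
            rs[i] = pearson_lastaxis(x[: x.size - lag], y[lag:])
        else:
            rs[i] = pearson_lastaxis(x[-lag:], y[: x.size + lag])
    if np.all(np.isnan(rs)):
        raise ValueError("zero-variance timecourse in every overlap")
    peak = int(np.nanargmax(rs))
    if peak == 0 or peak == lags.size - 1:
        logger.warning("xcorr_lag: peak at lag-range boundary, no interpolation")
        return float(lags[peak] * tr), float(rs[peak])
    offset = _quadratic_vertex(rs[peak - 1], rs[peak], rs[peak + 1])
    return float((lags[peak] + offset) * tr), float(rs[peak])


def hmm_behavior_match(gamma: np.ndarray, behav_boundary_tc: np.ndarray) -> float:
    """Lag-0 Pearson r between the gamma-derived boundary timecourse and a
    behavioral boundary timecourse on the same TR grid. NaN (with a log
    message) when the gamma timecourse is constant."""
    brain_tc = boundary_timecourse_from_gamma(gamma)
    behav = np.asarray(behav_boundary_tc, dtype=float)
    if brain_tc.shape != behav.shape:
        raise ValueError("timecourse length mismatch")
    if np.std(behav) == 0:
        raise ValueError("zero-variance behavioral timecourse")
    r = pearson_lastaxis(brain_tc, behav)
    if np.isnan(r):
        logger.info("hmm_behavior_match: constant gamma timecourse -> undefined r")
    return float(r)
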
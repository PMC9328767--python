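"""Behavioral boundary processing and boundary-evoked ROI response analysis.

Rater annotations (boundary times in seconds) are turned into a regressor on
the TR grid by counting annotations per TR bin and convolving with a
hemodynamic response function — the one-parameter gamma kernel

    h(t) = (t / (p q))**p * exp(p - t / q),   p = 8.6, q = 0.547 s,

which peaks at exactly 1 when t = p q ~= 4.7 s. ROI timecourses (e.g.
hippocampus) are then correlated with this regressor at delays of up to 10 s,
and the per-subject boundary correlation is related to age with an ordinary
Pearson test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._utils import logger, pearson_lastaxis
from .datatypes import AnnotationSet, Rater

HRF_PEAK_SHAPE_P = 8.6
HRF_SCALE_Q_S = 0.547


def hrf_kernel(
    tr: float,
    peak_shape_p: float = HRF_PEAK_SHAPE_P,
    scale_q: float = HRF_SCALE_Q_S,
    duration: float = 25.0,
) -> np.ndarray:
    """Gamma-variate HRF sampled on the TR grid from 0 to `duration` seconds;
    non-negative, unimodal, unit peak at t = p*q (~4.704 s with defaults)."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    p, q = peak_shape_p, scale_q
    with np.errstate(divide="ignore"):
        h = (t / (p * q)) ** p * np.exp(p - t / q)
    h[t == 0] = 0.0
    return h


def annotation_counts(annotations: AnnotationSet, T: int, tr: float) -> np.ndarray:
    """Number of boundary annotations (all raters pooled) per TR bin; boundary
    times are binned by floor(time / tr), with times at exactly the stimulus
    end assigned to the last TR."""
    if annotations.duration_s > T * tr + 1e-9:
        raise ValueError("stimulus duration exceeds the timecourse span")
    counts = np.zeros(T)
    for rater in annotations.raters:
        if rater.boundaries_s.size and rater.boundaries_s[0] < 0:
            raise ValueError("negative boundary time")
        bins = np.minimum(np.floor(rater.boundaries_s / tr).astype(int), T - 1)
        np.add.at(counts, bins, 1.0)
    return counts


def convolve_boundaries(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Full-mode convolution of a count vector with an HRF kernel, truncated
    to the count vector's length."""
    counts = np.asarray(counts, dtype=float)
    return np.convolve(counts, np.asarray(kernel, dtype=float), mode="full")[: counts.size]


def boundary_timecourse(
    annotations: AnnotationSet, T: int, tr: float, **hrf_kwargs
) -> np.ndarray:
    """Convenience: HRF-convolved annotation-count regressor on the TR grid."""
    return convolve_boundaries(annotation_counts(annotations, T, tr), hrf_kernel(tr, **hrf_kwargs))


def filter_raters(
    annotations: AnnotationSet, min_median_event_s: float = 1.0
) -> AnnotationSet:
    """Drop raters whose median event duration (inter-boundary interval, with
    the stimulus start as the first segment origin) is below threshold.
    Raters with no recorded boundary are retained (the criterion targets
    spam clicking, which they cannot exhibit)."""
    kept = []
    for rater in annotations.raters:
        if rater.boundaries_s.size:
            intervals = np.diff(np.concatenate([[0.0], rater.boundaries_s]))
            if np.median(intervals) < min_median_event_s:
                logger.info("filter_raters: removing %s (median event %.2fs)",
                            rater.rater_id, float(np.median(intervals)))
                continue
        kept.append(rater)
    return AnnotationSet(duration_s=annotations.duration_s, raters=kept)


def consensus_boundaries(
    annotations: AnnotationSet,
    agreement: float = 0.5,
    window_s: float = 2.0,
    grid_step_s: float = 1.0,
) -> np.ndarray:
    """Boundary times where more than `agreement` of raters marked a boundary.

    On a regular grid the fraction of raters with at least one annotation
    within +/- window_s of each grid point is computed; maximal runs of grid
    points exceeding the agreement fraction are merged, each yielding one
    boundary at the run's count-weighted center.
    """
    if len(annotations) < 2:
        raise ValueError("consensus needs at least 2 raters")
    grid = np.arange(0.0, annotations.duration_s + 1e-9, grid_step_s)
    frac = np.zeros(grid.size)
    for rater in annotations.raters:
        if rater.boundaries_s.size == 0:
            continue
        near = np.min(np.abs(grid[:, None] - rater.boundaries_s[None, :]), axis=1)
        frac += near <= window_s
    frac /= len(annotations)
    above = frac > agreement
    out = []
    i = 0
    while i < grid.size:
        if above[i]:
            j = i
            while j + 1 < grid.size and above[j + 1]:
                j += 1
            w = frac[i : j + 1]
            out.append(float((grid[i : j + 1] * w).sum() / w.sum()))
            i = j + 1
        else:
            i += 1
    return np.asarray(out)


def lagged_boundary_correlation(
    roi_tc: np.ndarray,
    boundary_tc: np.ndarray,
    tr: float,
    max_lag_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between an ROI timecourse and the boundary regressor delayed
    by each integer-TR lag in [0, max_lag_s] (truncated overlap), as
    ``(lags_seconds, r_values)``; a zero-variance overlap yields NaN."""
    roi = np.asarray(roi_tc, dtype=float)
    btc = np.asarray(boundary_tc, dtype=float)
    if roi.shape != btc.shape:
        raise ValueError("timecourse length mismatch")
    n_lags = int(np.floor(max_lag_s / tr))
    lags = np.arange(n_lags + 1)
    rs = np.array(
        [pearson_lastaxis(roi[lag:], btc[: btc.size - lag] if lag else btc) for lag in lags]
    )
    return lags * tr, rs


def age_effect(per_subject_values, ages) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df) between a
    per-subject quantity (e.g. boundary correlation, ROI volume) and age."""
    v = np.asarray(per_subject_values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape or v.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.std(v) == 0 or np.std(a) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(v, a)
    return float(r), float(p)
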
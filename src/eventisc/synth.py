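"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analyses assume:
event-structured group signals shared across subjects, a tunable correlation
``rho_b`` between the two groups' mean signals, an integer-TR temporal lead of
one group over the other, independent per-subject Gaussian noise, noisy rater
annotations, and age-modulated boundary-locked ROI responses.

Under the signal-plus-noise model used throughout (subject = group signal +
iid noise with variance ``noise_sd**2`` on a unit-variance signal), the
expected pairwise inter-subject correlation is ``1 / (1 + noise_sd**2)``, which
makes parameter-recovery tests analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import child_seed, logger, zscore
from .datatypes import AnnotationSet, CohortDataset, Rater, Subject


@dataclass
class SimSpec:
    """Parameters of a two-group synthetic cohort.

    ``boundaries_tr`` are group-A event onsets; group B's onsets are the same
    indices minus ``shift_tr`` (clipped to [1, T-1]), so positive ``shift_tr``
    means group B leads in time.
    """

    n_parcels: int = 1
    n_features: int = 1
    n_timepoints: int = 750
    tr: float = 0.8
    n_subjects_per_group: int = 40
    n_male_per_group: int = 22
    age_range_a: tuple[float, float] = (5.0, 8.0)
    age_range_b: tuple[float, float] = (16.0, 19.0)
    noise_sd: float = 2.0
    rho_b: float = 1.0
    shift_tr: int = 0
    boundaries_tr: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        b = np.asarray(self.boundaries_tr, dtype=int)
        if b.size and not (
            np.all(np.diff(b) > 0) and b[0] > 0 and b[-1] < self.n_timepoints
        ):
            raise ValueError("boundaries must be strictly increasing within (0, T)")
        if abs(self.rho_b) > 1:
            raise ValueError("|rho_b| must be <= 1")
        if self.n_male_per_group > self.n_subjects_per_group:
            raise ValueError("n_male exceeds group size")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    group_signals: dict[str, np.ndarray]  # group -> (parcels, features, time)
    true_boundaries_tr: dict[str, np.ndarray]
    rho_b: float
    rater_boundary_times_s: list[np.ndarray] = field(default_factory=list)
    age_effect_slope: float = 0.0


def make_event_patterns(
    K: int, V: int, seed: int, orthogonal: bool = False
) -> np.ndarray:
    """Draw K event patterns of length V, z-scored across features.

    With ``orthogonal=True`` the patterns are orthogonalized by QR before
    z-scoring, which requires K <= V.
    """
    if K < 2 or V < 2:
        raise ValueError("need K >= 2 and V >= 2")
    if orthogonal and K > V:
        raise ValueError(f"cannot orthogonalize K={K} patterns in V={V} dimensions")
    rng = np.random.default_rng(seed)
    pats = rng.standard_normal((K, V))
    if orthogonal:
        q, _ = np.linalg.qr(pats.T)
        pats = q.T[:K]
    return zscore(pats, axis=1)


def make_group_signal(
    patterns: np.ndarray, boundaries_tr, T: int
) -> np.ndarray:
    """Piecewise-constant (features, time) signal: column t carries the pattern
    of the event containing t (event index = #boundaries <= t)."""
    patterns = np.asarray(patterns, dtype=float)
    b = np.asarray(boundaries_tr, dtype=int)
    if b.size == 0:
        logger.info("make_group_signal: empty boundary list, single-event signal")
    elif b[0] <= 0 or b[-1] >= T:
        raise ValueError("boundaries must lie within (0, T)")
    labels = np.searchsorted(b, np.arange(T), side="right")
    if labels.max() >= patterns.shape[0]:
        raise ValueError("more segments than patterns")
    return patterns[labels].T  # (V, T)


def event_labels(boundaries_tr, T: int) -> np.ndarray:
    """1-based event label per timepoint for a boundary list."""
    b = np.asarray(boundaries_tr, dtype=int)
    return np.searchsorted(b, np.arange(T), side="right") + 1


def make_correlated_group_signal(
    signal_a: np.ndarray, rho_b: float, seed: int
) -> np.ndarray:
    """Mix a z-scored copy of ``signal_a`` with an independent unit-variance
    process so the per-feature population correlation equals ``rho_b``."""
    if abs(rho_b) > 1:
        raise ValueError("|rho_b| must be <= 1")
    signal_a = np.asarray(signal_a, dtype=float)
    za = zscore(signal_a, axis=-1)
    rng = np.random.default_rng(seed)
    u = zscore(rng.standard_normal(signal_a.shape), axis=-1)
    return rho_b * za + np.sqrt(1.0 - rho_b**2) * u


def make_subjects(
    group_signal: np.ndarray, n: int, noise_sd: float, seed: int
) -> list[np.ndarray]:
    """n copies of the group signal plus iid Gaussian noise(0, noise_sd**2)."""
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    group_signal = np.asarray(group_signal, dtype=float)
    rng = np.random.default_rng(seed)
    return [
        group_signal + noise_sd * rng.standard_normal(group_signal.shape)
        for _ in range(n)
    ]


def make_annotations(
    true_boundaries_s,
    n_raters: int,
    jitter_sd_s: float,
    miss_rate: float,
    seed: int,
    duration_s: float,
    rater_ages=None,
) -> AnnotationSet:
    """Noisy rater annotations: each rater keeps each true boundary with
    probability 1 - miss_rate and jitters it by Gaussian noise, clipped to the
    stimulus duration."""
    if not (0 <= miss_rate < 1):
        raise ValueError("miss_rate must be in [0, 1)")
    if jitter_sd_s < 0:
        raise ValueError("jitter_sd_s must be non-negative")
    tb = np.asarray(true_boundaries_s, dtype=float)
    rng = np.random.default_rng(seed)
    if rater_ages is None:
        rater_ages = rng.uniform(18.0, 45.0, size=n_raters)
    raters = []
    for i in range(n_raters):
        keep = rng.random(tb.size) >= miss_rate
        times = tb[keep] + jitter_sd_s * rng.standard_normal(int(keep.sum()))
        times = np.clip(times, 0.0, duration_s)
        raters.append(Rater(f"rater{i:02d}", float(rater_ages[i]), np.sort(times)))
    return AnnotationSet(duration_s=duration_s, raters=raters)


def make_boundary_locked_roi(
    ages,
    boundary_tc: np.ndarray,
    base_gain: float,
    slope_per_year: float,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Per-subject ROI timecourses whose boundary-locked gain varies with age.

    subject i = (base_gain + slope_per_year * (age_i - mean age)) * boundary_tc
    + Gaussian noise.  The population correlation between age and the
    per-subject boundary correlation has the sign of ``slope_per_year``
    (visible only when noise_sd > 0, since correlation is scale-invariant).
    """
    ages = np.asarray(ages, dtype=float)
    boundary_tc = np.asarray(boundary_tc, dtype=float)
    gains = base_gain + slope_per_year * (ages - ages.mean())
    if np.any(gains < 0):
        raise ValueError(
            "slope_per_year yields negative gains over this age range"
        )
    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal((ages.size, boundary_tc.size))
    return gains[:, None] * boundary_tc[None, :] + noise


def _assign_demographics(spec: SimSpec, rng, group: str, age_range):
    n = spec.n_subjects_per_group
    genders = np.array(["M"] * spec.n_male_per_group + ["F"] * (n - spec.n_male_per_group))
    rng.shuffle(genders)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    return ages, genders


def make_cohort(spec: SimSpec) -> tuple[CohortDataset, GroundTruth]:
    """Full two-group cohort ("A", "B") per the SimSpec, with ground truth.

    Group A's signal is piecewise constant over ``boundaries_tr``; group B's
    structured signal uses the same patterns at boundaries shifted earlier by
    ``shift_tr`` TRs, then mixed with an independent process to correlation
    ``rho_b``. Every parcel carries an independent pattern draw.
    """
    T = spec.n_timepoints
    b_a = np.asarray(spec.boundaries_tr, dtype=int)
    b_b = np.clip(b_a - spec.shift_tr, 1, T - 1) if b_a.size else b_a
    K = b_a.size + 1

    sig_a = np.empty((spec.n_parcels, spec.n_features, T))
    sig_b = np.empty_like(sig_a)
    for p in range(spec.n_parcels):
        if K >= 2 and spec.n_features >= 2:
            pats = make_event_patterns(K, spec.n_features, child_seed(spec.seed, 0, p))
        else:
            pats = np.random.default_rng(child_seed(spec.seed, 0, p)).standard_normal(
                (K, spec.n_features)
            )
        struct_a = make_group_signal(pats, b_a, T)
        struct_b = make_group_signal(pats, b_b, T)
        sig_a[p] = zscore(struct_a, axis=-1)
        sig_b[p] = make_correlated_group_signal(
            struct_b, spec.rho_b, child_seed(spec.seed, 1, p)
        )

    rng = np.random.default_rng(child_seed(spec.seed, 2))
    subjects = []
    for group, sig, age_range, stream in (
        ("A", sig_a, spec.age_range_a, 3),
        ("B", sig_b, spec.age_range_b, 4),
    ):
        ages, genders = _assign_demographics(spec, rng, group, age_range)
        mats = make_subjects(
            sig, spec.n_subjects_per_group, spec.noise_sd, child_seed(spec.seed, stream)
        )
        for i, mat in enumerate(mats):
            subjects.append(
                Subject(f"{group}{i:03d}", float(ages[i]), str(genders[i]), group, mat)
            )

    truth = GroundTruth(
        group_signals={"A": sig_a, "B": sig_b},
        true_boundaries_tr={"A": b_a, "B": b_b},
        rho_b=spec.rho_b,
    )
    return CohortDataset(subjects, tr=spec.tr), truth
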
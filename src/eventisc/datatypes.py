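"""Core containers for cohorts, annotations, and fitted event models.

Timecourses are indexed in TRs internally (0-based); user-facing lags and
durations are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_pvt


@dataclass
class Subject:
    """One participant: metadata plus a (parcels, time) or (parcels, features, time) array."""

    subject_id: str
    age: float
    gender: str
    group: str
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite data")

    @property
    def pvt(self) -> np.ndarray:
        """Data in canonical (parcels, features, time) layout."""
        return as_pvt(self.data)


@dataclass
class CohortDataset:
    """A set of subjects sharing array dimensions and TR."""

    subjects: list[Subject]
    tr: float

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        shapes = {s.pvt.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError(f"subjects have mismatched shapes: {shapes}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_parcels(self) -> int:
        return self.subjects[0].pvt.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].pvt.shape[2]

    def stack(self) -> np.ndarray:
        """All subjects as a (n_subjects, parcels, features, time) array."""
        return np.stack([s.pvt for s in self.subjects])

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "age_years": [s.age for s in self.subjects],
                "gender": [s.gender for s in self.subjects],
                "group": [s.group for s in self.subjects],
            }
        )

    def select(self, subject_ids) -> "CohortDataset":
        wanted = list(subject_ids)
        by_id = {s.subject_id: s for s in self.subjects}
        return CohortDataset([by_id[i] for i in wanted], tr=self.tr)

    def groups(self) -> dict[str, "CohortDataset"]:
        out: dict[str, list[Subject]] = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s)
        return {g: CohortDataset(subs, tr=self.tr) for g, subs in out.items()}


@dataclass
class Rater:
    rater_id: str
    age: float
    boundaries_s: np.ndarray

    def __post_init__(self):
        self.boundaries_s = np.sort(np.asarray(self.boundaries_s, dtype=float))


@dataclass
class AnnotationSet:
    """Rater-wise event-boundary times (seconds) for one stimulus."""

    duration_s: float
    raters: list[Rater]

    def __post_init__(self):
        for r in self.raters:
            if r.boundaries_s.size and (
                r.boundaries_s[0] < 0 or r.boundaries_s[-1] > self.duration_s
            ):
                raise ValueError(
                    f"rater {r.rater_id}: boundary outside [0, {self.duration_s}]"
                )

    def __len__(self) -> int:
        return len(self.raters)


@dataclass
class EventSegModel:
    """Ordered-event HMM: K event patterns, shared emission variance."""

    K: int
    patterns: np.ndarray  # (K, V) event mean patterns
    noise_var: float
    train_loglik: float  # per-timepoint-per-feature normalized
    K_grid: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("non-finite event patterns")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
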
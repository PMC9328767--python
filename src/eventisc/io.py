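"""On-disk formats and run configuration.

Timecourses are stored as one delimited text file per subject (parcels as
rows, TRs as columns) with a format-version header line; subject metadata,
annotations and ROI timecourses are plain CSV; ground truth and results are
JSON. Everything round-trips bit-exactly at float precision ``%.17g``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import logger
from .datatypes import AnnotationSet, CohortDataset, Rater, Subject

TIMECOURSE_MAGIC = "# eventisc-timecourse v1"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (paths, acquisition, analysis knobs)."""

    data_dir: str
    output_dir: str
    metadata_csv: str = "metadata.csv"
    annotations_csv: str | None = None
    roi_csv: str | None = None
    tr: float = 0.8
    groups: dict = field(default_factory=lambda: {"A": [5.0, 8.0], "B": [16.0, 19.0]})
    subsample_n: int = 40
    subsample_n_male: int = 22
    n_subsamples: int = 5
    k_grid: list = field(default_factory=lambda: [2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50])
    structure_threshold: float = 0.002
    fdr_q: float = 0.05
    n_perm_initial: int = 100
    n_perm_increment: int = 1000
    n_perm_max: int = 6000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_timecourse(path, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:  # (P, V, T) flattened to (P*V, T); V recorded in header
        header = f"{TIMECOURSE_MAGIC}\n# shape {data.shape[0]} {data.shape[1]} {data.shape[2]}"
        flat = data.reshape(-1, data.shape[2])
    else:
        header = f"{TIMECOURSE_MAGIC}\n# shape {data.shape[0]} 1 {data.shape[1]}"
        flat = data
    np.savetxt(path, flat, fmt="%.17g", delimiter="\t", header=header, comments="")


def read_timecourse(path) -> np.ndarray:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != TIMECOURSE_MAGIC:
            raise ValueError(f"{path}: not an eventisc timecourse file")
        shape = tuple(int(x) for x in fh.readline().split()[2:])
        flat = np.loadtxt(fh, delimiter="\t", ndmin=2)
    p, v, t = shape
    data = flat.reshape(p, v, t)
    return data[:, 0, :] if v == 1 else data


def write_cohort(cohort: CohortDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.metadata().to_csv(directory / "metadata.csv", index=False)
    for s in cohort.subjects:
        write_timecourse(directory / f"{s.subject_id}.tsv", s.data)


def read_cohort(directory, tr: float, metadata_csv: str = "metadata.csv") -> CohortDataset:
    """Load a cohort written by :func:`write_cohort`. Subjects whose files are
    missing, contain NaNs, or disagree on dimensions are rejected with a
    per-file report; the run continues with the rest."""
    directory = Path(directory)
    meta = pd.read_csv(directory / metadata_csv)
    if meta.empty:
        raise ValueError("empty metadata table")
    if meta["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in metadata")
    loaded, rejected = [], []
    for _, row in meta.iterrows():
        path = directory / f"{row.subject_id}.tsv"
        try:
            data = read_timecourse(path)
            if not np.all(np.isfinite(data)):
                raise ValueError("non-finite values")
            loaded.append(
                Subject(str(row.subject_id), float(row.age_years), str(row.gender),
                        str(row.group), data)
            )
        except (OSError, ValueError) as exc:
            rejected.append((str(row.subject_id), str(exc)))
    # dimension check against the majority shape, so one corrupt file cannot
    # take the whole cohort down with it
    if loaded:
        shapes = [s.pvt.shape for s in loaded]
        majority = max(set(shapes), key=shapes.count)
        subjects = [s for s in loaded if s.pvt.shape == majority]
        rejected += [
            (s.subject_id, f"shape {s.pvt.shape} != {majority}")
            for s in loaded
            if s.pvt.shape != majority
        ]
    else:
        subjects = []
    for sid, reason in rejected:
        logger.warning("read_cohort: rejected %s (%s)", sid, reason)
    if not subjects:
        raise ValueError("no loadable subjects")
    return CohortDataset(subjects, tr=tr)


def write_annotations(annotations: AnnotationSet, path) -> None:
    rows = [
        {"rater_id": r.rater_id, "age_years": r.age, "boundary_time_s": t}
        for r in annotations.raters
        for t in r.boundaries_s
    ]
    # raters without boundaries keep a sentinel row so they round-trip
    for r in annotations.raters:
        if r.boundaries_s.size == 0:
            rows.append({"rater_id": r.rater_id, "age_years": r.age, "boundary_time_s": np.nan})
    df = pd.DataFrame(rows, columns=["rater_id", "age_years", "boundary_time_s"])
    df.attrs["duration_s"] = annotations.duration_s
    with open(path, "w") as fh:
        fh.write(f"# duration_s={annotations.duration_s}\n")
        df.to_csv(fh, index=False)


def read_annotations(path) -> AnnotationSet:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# duration_s="):
            raise ValueError(f"{path}: missing duration header")
        duration = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    raters = []
    for (rid, age), sub in df.groupby(["rater_id", "age_years"], sort=False):
        times = sub["boundary_time_s"].dropna().to_numpy()
        raters.append(Rater(str(rid), float(age), times))
    return AnnotationSet(duration_s=duration, raters=raters)


def read_roi_csv(path) -> pd.DataFrame:
    """ROI table: subject_id, roi_name, voxel_count, then T timecourse columns."""
    df = pd.read_csv(path)
    required = {"subject_id", "roi_name", "voxel_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI CSV must contain columns {sorted(required)}")
    return df


def roi_timecourses(df: pd.DataFrame, roi_name: str) -> tuple[list, np.ndarray, np.ndarray]:
    """(subject ids, voxel counts, (n_subjects, T) timecourses) for one ROI."""
    sub = df[df["roi_name"] == roi_name]
    tc_cols = [c for c in df.columns if c.startswith("t")]
    return (
        sub["subject_id"].tolist(),
        sub["voxel_count"].to_numpy(float),
        sub[tc_cols].to_numpy(float),
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
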
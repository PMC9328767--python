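"""End-to-end orchestration of the analysis on a loaded (or simulated) cohort.

Stages run in the order the analysis is reported: within-group ISC, the
between-group ISC test, event-structure screening plus joint HMM fitting,
event-timing statistics, and behavioral/ROI boundary-response analyses.
Each stage writes CSV/JSON under the output directory and records itself in a
manifest (config hash, seeds, per-file SHA-256); a stage failure is recorded
and later independent stages still run.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_seed, logger
from .boundaries import (
    age_effect,
    boundary_timecourse,
    consensus_boundaries,
    filter_raters,
    lagged_boundary_correlation,
)
from .datatypes import CohortDataset
from .hmm import (
    event_structure_index,
    joint_fit,
    select_k,
    snap_to_grid,
)
from .inference import isc_b_test, timing_difference_test
from .io import (
    RunConfig,
    read_annotations,
    read_cohort,
    read_roi_csv,
    roi_timecourses,
    sha256_file,
)
from .isc import expected_loo_from_sh, expected_pw_from_sh, loo_isc, split_half_isc, subsample_average
from .perm import PermutationPlan, bh_fdr, gender_matched_subsample
from .timing import xcorr_lag


def _parcel_subjects(group: CohortDataset, parcel: int):
    """Per-subject (V, T) arrays for one parcel."""
    return [s.pvt[parcel] for s in group.subjects]


def _plan(config: RunConfig, seed_stream: int) -> PermutationPlan:
    return PermutationPlan(
        n_initial=config.n_perm_initial,
        increment=config.n_perm_increment,
        max_total=config.n_perm_max,
        alpha=config.fdr_q,
        n_subsamples=config.n_subsamples,
        seed=child_seed(config.seed, seed_stream),
    )


def _subsampling_feasible(cohort: CohortDataset, config: RunConfig) -> bool:
    meta = cohort.metadata()
    for g in meta["group"].unique():
        sub = meta[meta["group"] == g]
        males = (sub["gender"] == "M").sum()
        if males < config.subsample_n_male or len(sub) - males < config.subsample_n - config.subsample_n_male:
            return False
    return True


def stage_isc(cohort: CohortDataset, config: RunConfig, outdir: Path) -> dict:
    """Within-group split-half ISC (subsample-averaged where feasible),
    leave-one-out ISC, and the closed-form pairwise/LOO conversions."""
    use_subsample = _subsampling_feasible(cohort, config)
    rows = []
    for gname, group in sorted(cohort.groups().items()):
        if use_subsample:
            subsample_fn = lambda ds, s, g=gname: gender_matched_subsample(
                ds.metadata(), g, config.subsample_n, config.subsample_n_male, s
            )
            n_eff = config.subsample_n
        else:
            logger.info("stage_isc: groups too small for gender-matched subsampling, using full groups")
            subsample_fn = None
            n_eff = len(group) - (len(group) % 2)
        sh_mean, _ = subsample_average(
            lambda ds, s: split_half_isc(ds, s),
            group,
            n_subsamples=config.n_subsamples,
            seeds=[child_seed(config.seed, 10, i) for i in range(config.n_subsamples)],
            subsample_fn=subsample_fn,
        )
        loo = loo_isc(group).mean(axis=0)
        for parcel in range(cohort.n_parcels):
            sh = float(sh_mean[parcel])
            rows.append(
                {
                    "group": gname,
                    "parcel": parcel,
                    "shISC": sh,
                    "looISC_direct": float(loo[parcel]),
                    "pwISC_from_sh": expected_pw_from_sh(sh, n_eff) if np.isfinite(sh) else np.nan,
                    "looISC_from_sh": expected_loo_from_sh(sh, n_eff) if np.isfinite(sh) else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "isc.csv", index=False)
    return {"files": ["isc.csv"], "n_groups": df["group"].nunique()}


def stage_iscb(cohort: CohortDataset, config: RunConfig, outdir: Path) -> dict:
    """Between-group ISC with lower-tail permutation inference and BH-FDR."""
    groups = sorted(cohort.groups())
    if len(groups) != 2:
        raise ValueError("stage_iscb expects exactly two groups")
    use_subsample = _subsampling_feasible(cohort, config)
    res = isc_b_test(
        cohort,
        groups[0],
        groups[1],
        _plan(config, 20),
        subsample_n=config.subsample_n if use_subsample else None,
        subsample_n_male=config.subsample_n_male if use_subsample else None,
        seed=child_seed(config.seed, 21),
    )
    qvals, sig = bh_fdr(res.p, config.fdr_q)
    df = pd.DataFrame(
        {
            "parcel": np.arange(cohort.n_parcels),
            "statistic": "ISC_b",
            "value": np.atleast_1d(res.observed),
            "n_perms": res.n_perms,
            "p": res.p,
            "q": qvals,
            "significant": sig,
        }
    )
    df.to_csv(outdir / "iscb.csv", index=False)
    return {"files": ["iscb.csv"], "n_perms": res.n_perms}


def stage_hmm(cohort: CohortDataset, config: RunConfig, outdir: Path) -> dict:
    """Per-parcel, per-group event-count selection and structure screening;
    joint fit at the snapped K for parcels with structure in either group."""
    groups = sorted(cohort.groups().items())
    if len(groups) != 2:
        raise ValueError("stage_hmm expects exactly two groups")
    (la, ga), (lb, gb) = groups
    rows = []
    joint = {}
    for parcel in range(cohort.n_parcels):
        subj_a = _parcel_subjects(ga, parcel)
        subj_b = _parcel_subjects(gb, parcel)
        seed_p = child_seed(config.seed, 30, parcel)
        k_a = select_k(subj_a, config.k_grid, seed=seed_p)
        k_b = select_k(subj_b, config.k_grid, seed=seed_p)
        idx_a = event_structure_index(subj_a, config.k_grid, seed=seed_p)
        idx_b = event_structure_index(subj_b, config.k_grid, seed=seed_p)
        structured = (idx_a >= config.structure_threshold) or (idx_b >= config.structure_threshold)
        row = {
            "parcel": parcel,
            f"K_{la}": k_a,
            f"K_{lb}": k_b,
            f"structure_index_{la}": idx_a,
            f"structure_index_{lb}": idx_b,
            "structured": structured,
        }
        if structured:
            K = snap_to_grid((k_a + k_b) / 2.0, config.k_grid)
            fit = joint_fit(subj_a, subj_b, K, seed=seed_p, labels=(la, lb))
            joint[parcel] = fit
            row.update(
                {
                    "K_joint": K,
                    f"heldout_loglik_{la}": fit.heldout_loglik[la],
                    f"heldout_loglik_{lb}": fit.heldout_loglik[lb],
                }
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "hmm.csv", index=False)
    return {"files": ["hmm.csv"], "joint_fits": joint, "labels": (la, lb)}


def stage_timing(
    cohort: CohortDataset,
    config: RunConfig,
    outdir: Path,
    joint_fits: dict,
    labels: tuple[str, str],
    behav_tc: np.ndarray | None,
) -> dict:
    """Anticipation-score differences with permutation inference; optional
    cross-correlation lag of each group's boundary timecourse vs behavior."""
    la, lb = labels
    groups = cohort.groups()
    ga, gb = groups[la], groups[lb]
    rows = []
    for parcel, fit in joint_fits.items():
        seed_p = child_seed(config.seed, 40, parcel)
        res = timing_difference_test(
            _parcel_subjects(ga, parcel),
            _parcel_subjects(gb, parcel),
            fit.model.K,
            _plan(config, 41),
            seed=seed_p,
        )
        row = {
            "parcel": parcel,
            "anticipation_diff": float(np.atleast_1d(res.observed)[0]),
            "p": float(res.p[0]),
            "n_perms": res.n_perms,
        }
        if behav_tc is not None:
            from .hmm import boundary_timecourse_from_gamma

            for lab in (la, lb):
                lag_s, r_pk = xcorr_lag(
                    boundary_timecourse_from_gamma(fit.gamma[lab]),
                    behav_tc,
                    max_lag_tr=min(30, cohort.n_timepoints // 4),
                    tr=cohort.tr,
                )
                row[f"lag_s_{lab}"] = lag_s
                row[f"r_peak_{lab}"] = r_pk
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        qvals, sig = bh_fdr(df["p"].to_numpy(), config.fdr_q)
        df["q"] = qvals
        df["significant"] = sig
    df.to_csv(outdir / "timing.csv", index=False)
    return {"files": ["timing.csv"], "n_parcels_tested": len(df)}


def stage_boundary(cohort: CohortDataset, config: RunConfig, outdir: Path) -> dict:
    """Rater QC, consensus boundaries, the HRF-convolved boundary regressor,
    and (when ROI timecourses are provided) lagged boundary correlations with
    their age effect."""
    ann = read_annotations(Path(config.data_dir) / config.annotations_csv)
    ann = filter_raters(ann)
    consensus = consensus_boundaries(ann)
    T, tr = cohort.n_timepoints, cohort.tr
    btc = boundary_timecourse(ann, T, tr)
    np.savetxt(outdir / "boundary_timecourse.tsv", btc, fmt="%.17g")
    out = {
        "n_raters_kept": len(ann),
        "consensus_boundaries_s": [float(x) for x in consensus],
        "files": ["boundary_timecourse.tsv", "boundary_summary.json"],
    }
    if config.roi_csv:
        roi_df = read_roi_csv(Path(config.data_dir) / config.roi_csv)
        meta = cohort.metadata().set_index("subject_id")
        rows = []
        for roi_name in roi_df["roi_name"].unique():
            ids, voxels, tcs = roi_timecourses(roi_df, roi_name)
            ages = meta.loc[ids, "age_years"].to_numpy(float)
            lag0 = []
            for sid, tc in zip(ids, tcs):
                lags_s, rs = lagged_boundary_correlation(tc, btc, tr)
                lag0.append(rs[0])
                rows.append(
                    {"subject_id": sid, "roi_name": roi_name,
                     **{f"r_lag_{ls:.1f}s": r for ls, r in zip(lags_s, rs)}}
                )
            r_age, p_age = age_effect(lag0, ages)
            r_vol, p_vol = age_effect(voxels, ages)
            out[f"age_effect_{roi_name}"] = {"r": r_age, "p": p_age}
            out[f"volume_age_{roi_name}"] = {"r": r_vol, "p": p_vol}
        pd.DataFrame(rows).to_csv(outdir / "roi_lagged_correlations.csv", index=False)
        out["files"].append("roi_lagged_correlations.csv")
    with open(outdir / "boundary_summary.json", "w") as fh:
        json.dump({k: v for k, v in out.items() if k != "files"}, fh, indent=2)
    return out


def run_pipeline(config: RunConfig, cohort: CohortDataset | None = None) -> dict:
    """Run all stages, writing outputs and a manifest under the output dir.

    Stage failures are recorded in the manifest; later stages that do not
    depend on the failed one still run.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = read_cohort(config.data_dir, tr=config.tr, metadata_csv=config.metadata_csv)

    manifest: dict = {"config": config.to_dict(), "config_hash": config.hash(), "stages": {}}
    hmm_out = None
    behav_tc = None

    def run_stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
            manifest["stages"][name] = {"status": "ok",
                                        **{k: v for k, v in result.items()
                                           if k not in ("joint_fits", "labels")}}
            return result
        except Exception as exc:  # recorded, independent stages continue
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                        "traceback": traceback.format_exc(limit=3)}
            return None

    run_stage("isc", stage_isc, cohort, config, outdir)
    run_stage("iscb", stage_iscb, cohort, config, outdir)
    hmm_out = run_stage("hmm", stage_hmm, cohort, config, outdir)
    if config.annotations_csv:
        b_out = run_stage("boundary", stage_boundary, cohort, config, outdir)
        if b_out is not None:
            behav_tc = np.loadtxt(outdir / "boundary_timecourse.tsv")
    if hmm_out is not None:
        run_stage(
            "timing", stage_timing, cohort, config, outdir,
            hmm_out["joint_fits"], hmm_out["labels"], behav_tc,
        )

    manifest["output_hashes"] = {
        f.name: sha256_file(f) for f in sorted(outdir.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
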
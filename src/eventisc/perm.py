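"""Gender-matched subsampling, group-label permutation, and FDR control.

Inference on group differences proceeds by permuting group labels across
subjects while preserving each group's gender composition (labels are
shuffled within gender strata), re-computing the statistic on the permuted
groups, and comparing the observed value with the permutation null. The
permutation schedule is adaptive: an initial batch of permutations is run,
and while any parcel still has an exceedance proportion below alpha, batches
are added up to a hard cap; if after the cap a parcel has no exceedances at
all, the observed value itself is appended to the null (so p >= 1/(N+1)).
Multiple comparisons across parcels are controlled by Benjamini-Hochberg FDR.

Sidedness is registered per statistic: between-group ISC is tested on the
lower tail (significantly SMALLER than its null), while ISC differences,
model-fit differences and timing differences are two-sided via the absolute
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._utils import child_seed


@dataclass
class PermutationPlan:
    n_initial: int = 100
    increment: int = 1000
    max_total: int = 6000
    alpha: float = 0.05
    n_subsamples: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_initial > self.max_total or self.increment <= 0:
            raise ValueError("invalid permutation plan")


# fixed plan used for behavioral (rater) analyses
BEHAVIOR_PLAN = PermutationPlan(n_initial=10000, increment=1, max_total=10000)


def gender_matched_subsample(
    metadata: pd.DataFrame, group: str, n: int = 40, n_male: int = 22, seed: int = 0
) -> list:
    """Uniform random draw of exactly `n_male` males and `n - n_male` others
    from one group of a subject metadata table."""
    g = metadata[metadata["group"] == group]
    males = g[g["gender"] == "M"]["subject_id"].to_numpy()
    others = g[g["gender"] != "M"]["subject_id"].to_numpy()
    if len(males) < n_male or len(others) < n - n_male:
        raise ValueError(
            f"group {group}: need {n_male} males and {n - n_male} others, "
            f"have {len(males)} and {len(others)}"
        )
    rng = np.random.default_rng(seed)
    pick = np.concatenate(
        [rng.choice(males, n_male, replace=False), rng.choice(others, n - n_male, replace=False)]
    )
    return list(pick)


def permute_group_labels(metadata: pd.DataFrame, seed: int) -> pd.Series:
    """Shuffle group labels across subjects within each gender stratum, so
    every permuted group keeps its original gender composition. The same seed
    reproduces the same permuted labeling (reused across subsamples of one
    permutation index)."""
    rng = np.random.default_rng(seed)
    permuted = metadata["group"].copy()
    for _, idx in metadata.groupby("gender").groups.items():
        labels = metadata.loc[idx, "group"].to_numpy()
        permuted.loc[idx] = rng.permutation(labels)
    return permuted


def _exceedances(null: np.ndarray, observed: np.ndarray, side: str) -> np.ndarray:
    # undefined (NaN) null draws are counted as exceedances: they carry no
    # evidence that the observed value is extreme, so this is conservative
    if side == "two-sided":
        null = np.where(np.isnan(null), np.inf, null)
        return (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    if side == "greater":
        null = np.where(np.isnan(null), np.inf, null)
        return (null >= observed[None, :]).sum(axis=0)
    if side == "less":
        null = np.where(np.isnan(null), -np.inf, null)
        return (null <= observed[None, :]).sum(axis=0)
    raise ValueError(f"unknown side {side!r}")


def adaptive_p(
    statistic_fn,
    observed,
    plan: PermutationPlan,
    side: str = "two-sided",
) -> tuple[np.ndarray, int, np.ndarray]:
    """Adaptive permutation p-values for a vector-valued statistic.

    ``statistic_fn(perm_index, perm_seed)`` must return the statistic (array
    like ``observed``) computed under the permuted labeling identified by
    ``perm_seed`` (pass the seed to :func:`permute_group_labels` and reuse it
    across subsamples). Batches are added while any element's exceedance
    proportion is below ``plan.alpha`` and budget remains; elements with zero
    exceedances at the cap get the observed value appended to their null.
    Returns ``(p_values, n_perms_used, null_draws)``.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    defined = ~np.isnan(observed)  # undefined statistics get NaN p-values
    draws: list[np.ndarray] = []

    def _run_to(target: int):
        for i in range(len(draws), min(target, plan.max_total)):
            draws.append(
                np.atleast_1d(
                    np.asarray(statistic_fn(i, child_seed(plan.seed, 7, i)), dtype=float)
                )
            )

    _run_to(plan.n_initial)
    exceed = _exceedances(np.stack(draws), observed, side)
    # batches are added only if some element looks significant after the
    # initial batch, and then until every element has at least one exceedance
    # (or the cap is reached)
    if np.any(exceed[defined] / len(draws) < plan.alpha):
        while len(draws) < plan.max_total:
            _run_to(len(draws) + plan.increment)
            exceed = _exceedances(np.stack(draws), observed, side)
            if np.all(exceed[defined] > 0):
                break
    null = np.stack(draws)
    n_done = len(draws)
    p = np.full(observed.size, np.nan)
    zero = defined & (exceed == 0)
    ok = defined & (exceed > 0)
    p[ok] = exceed[ok] / n_done
    p[zero] = 1.0 / (n_done + 1)  # observed value appended to its own null
    return p, n_done, null


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, significant mask).
    NaN p-values (undefined statistics) are excluded and stay NaN."""
    p = np.asarray(p_values, dtype=float)
    qvals = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qvals[ok] = qv
        sig[ok] = rej
    return qvals, sig
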
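"""Permutation tests that tie the event model and ISC statistics to the
group-label permutation machinery.

The HMM-based tests follow the frozen-model rule: event patterns and variance
are trained once per cross-validation fold on the TRUE (unpermuted) training
data, and each permutation only re-evaluates the held-out subjects under
shuffled group labels at the already-selected event count. Held-out labels
are shuffled within each fold (preserving group counts), which keeps both
labels represented in every fold under every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import child_seed, zscore
from .datatypes import CohortDataset
from .hmm import _fold_averages, _joint_em, fold_indices, held_out_loglik, posterior
from .isc import isc_b
from .perm import PermutationPlan, adaptive_p, gender_matched_subsample, permute_group_labels
from .timing import anticipation_score


@dataclass
class PermTestResult:
    observed: np.ndarray | float
    p: np.ndarray
    n_perms: int
    null: np.ndarray


def _stack(subjects) -> np.ndarray:
    return np.stack([np.asarray(d, dtype=float) for d in subjects])


class _FrozenJointEvaluator:
    """Per-fold joint models trained on true labels, re-evaluable on permuted
    held-out group assignments."""

    def __init__(self, group_a_subjects, group_b_subjects, K: int,
                 n_folds: int = 5, seed: int = 0):
        self.a = _stack(group_a_subjects)
        self.b = _stack(group_b_subjects)
        self.folds_a = fold_indices(self.a.shape[0], n_folds, seed)
        self.folds_b = fold_indices(self.b.shape[0], n_folds, seed)
        self.models = []
        for (tr_a, _), (tr_b, _) in zip(self.folds_a, self.folds_b):
            avg_a = zscore(self.a[tr_a].mean(axis=0), axis=-1)
            avg_b = zscore(self.b[tr_b].mean(axis=0), axis=-1)
            model, _ = _joint_em([avg_a, avg_b], K)
            self.models.append(model)

    def evaluate(self, perm_seed: int | None = None):
        """Fold-averaged held-out (gamma_a, gamma_b, loglik_a, loglik_b),
        optionally under a within-fold label shuffle."""
        rng = None if perm_seed is None else np.random.default_rng(perm_seed)
        gam_a, gam_b, ll_a, ll_b = [], [], [], []
        for model, (_, te_a), (_, te_b) in zip(self.models, self.folds_a, self.folds_b):
            xs = np.concatenate([self.a[te_a], self.b[te_b]])
            labels = np.array([0] * len(te_a) + [1] * len(te_b))
            if rng is not None:
                labels = rng.permutation(labels)
            avg_a = zscore(xs[labels == 0].mean(axis=0), axis=-1)
            avg_b = zscore(xs[labels == 1].mean(axis=0), axis=-1)
            gam_a.append(posterior(model, avg_a))
            gam_b.append(posterior(model, avg_b))
            ll_a.append(held_out_loglik(model, avg_a))
            ll_b.append(held_out_loglik(model, avg_b))
        return (
            np.mean(gam_a, axis=0),
            np.mean(gam_b, axis=0),
            float(np.mean(ll_a)),
            float(np.mean(ll_b)),
        )


def timing_difference_test(
    group_a_subjects,
    group_b_subjects,
    K: int,
    plan: PermutationPlan,
    n_folds: int = 5,
    seed: int = 0,
) -> PermTestResult:
    """Two-sided permutation test of the anticipation-score difference
    (group A minus group B) under a jointly fit, frozen event model."""
    ev = _FrozenJointEvaluator(group_a_subjects, group_b_subjects, K, n_folds, seed)
    ga, gb, _, _ = ev.evaluate()
    observed = anticipation_score(ga) - anticipation_score(gb)

    def stat(_i, perm_seed):
        pga, pgb, _, _ = ev.evaluate(perm_seed)
        return anticipation_score(pga) - anticipation_score(pgb)

    p, n, null = adaptive_p(stat, observed, plan, side="two-sided")
    return PermTestResult(observed=observed, p=p, n_perms=n, null=null)


def model_fit_difference_test(
    group_a_subjects,
    group_b_subjects,
    K: int,
    plan: PermutationPlan,
    n_folds: int = 5,
    seed: int = 0,
) -> PermTestResult:
    """Two-sided permutation test of the held-out log-likelihood difference
    (group A minus group B) under the frozen joint model."""
    ev = _FrozenJointEvaluator(group_a_subjects, group_b_subjects, K, n_folds, seed)
    _, _, la, lb = ev.evaluate()
    observed = la - lb

    def stat(_i, perm_seed):
        _, _, pla, plb = ev.evaluate(perm_seed)
        return pla - plb

    p, n, null = adaptive_p(stat, observed, plan, side="two-sided")
    return PermTestResult(observed=observed, p=p, n_perms=n, null=null)


def isc_b_test(
    cohort: CohortDataset,
    group_a: str,
    group_b: str,
    plan: PermutationPlan,
    subsample_n: int | None = None,
    subsample_n_male: int | None = None,
    seed: int = 0,
) -> PermTestResult:
    """Lower-tail permutation test of per-parcel ISC_b between two groups.

    The statistic is averaged over ``plan.n_subsamples`` gender-matched
    subsamples (or the full groups when subsampling is not requested); each
    permutation reuses one gender-stratified label shuffle across all
    subsamples of that permutation index.
    """
    meta = cohort.metadata()

    def averaged_iscb(labels) -> np.ndarray:
        relabeled = CohortDataset(
            [
                type(s)(s.subject_id, s.age, s.gender, lab, s.data)
                for s, lab in zip(cohort.subjects, labels)
            ],
            tr=cohort.tr,
        )
        vals = []
        for k in range(plan.n_subsamples):
            sub_seed = child_seed(seed, 3, k)
            groups = relabeled.groups()
            ga, gb = groups[group_a], groups[group_b]
            if subsample_n is not None:
                m = relabeled.metadata()
                ga = relabeled.select(
                    gender_matched_subsample(m, group_a, subsample_n, subsample_n_male, sub_seed)
                )
                gb = relabeled.select(
                    gender_matched_subsample(m, group_b, subsample_n, subsample_n_male,
                                             child_seed(seed, 4, k))
                )
            vals.append(isc_b(ga, gb, child_seed(seed, 5, k)))
        return np.mean(vals, axis=0)

    observed = averaged_iscb(meta["group"].to_numpy())

    def stat(_i, perm_seed):
        return averaged_iscb(permute_group_labels(meta, perm_seed).to_numpy())

    p, n, null = adaptive_p(stat, observed, plan, side="less")
    return PermTestResult(observed=observed, p=p, n_perms=n, null=null)
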
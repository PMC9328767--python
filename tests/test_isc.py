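"""ISC estimators: exact values, closed forms, and the between-group statistic."""

import numpy as np
import pytest

import eventisc as ev
from eventisc._utils import zscore
from eventisc.datatypes import CohortDataset, Subject


def _cohort_from_stack(stack, group="A", tr=0.8):
    subs = [
        Subject(f"{group}{i:03d}", 10.0, "M" if i % 2 else "F", group, mat)
        for i, mat in enumerate(stack)
    ]
    return CohortDataset(subs, tr=tr)


def _shared_signal_cohort(n=8, P=2, T=200, noise_sd=0.0, seed=0, group="A"):
    rng = np.random.default_rng(seed)
    sig = zscore(rng.standard_normal((P, T)), axis=-1)
    stack = [sig + noise_sd * rng.standard_normal((P, T)) for _ in range(n)]
    return _cohort_from_stack(stack, group=group), sig


class TestSplitHalf:
    def test_identical_subjects_give_one(self):
        cohort, _ = _shared_signal_cohort(noise_sd=0.0)
        np.testing.assert_allclose(ev.split_half_isc(cohort, seed=0), 1.0, atol=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        stack = [rng.standard_normal((20, 750)) for _ in range(8)]
        sh = ev.split_half_isc(_cohort_from_stack(stack), seed=0)
        # null SD of Pearson r is ~1/sqrt(T); 20 independent parcels average down
        assert abs(np.mean(sh)) < 3 * (1 / np.sqrt(750)) / np.sqrt(20)

    def test_matches_equicorrelated_closed_form(self):
        # pairwise r = 1/(1+noise^2) = 0.2 at noise_sd=2 -> shISC = m r/(1+(m-1)r)
        vals = [
            ev.split_half_isc(
                _shared_signal_cohort(n=40, P=1, T=750, noise_sd=2.0, seed=s)[0],
                seed=s,
            )[0]
            for s in range(10)
        ]
        assert abs(np.mean(vals) - 20 * 0.2 / (1 + 19 * 0.2)) < 0.03

    def test_too_few_subjects_rejected(self):
        cohort, _ = _shared_signal_cohort(n=3)
        with pytest.raises(ValueError):
            ev.split_half_isc(cohort, seed=0)

    def test_odd_count_drops_one(self):
        cohort, _ = _shared_signal_cohort(n=9)
        np.testing.assert_allclose(ev.split_half_isc(cohort, seed=0), 1.0, atol=1e-12)


class TestConversions:
    def test_zero_maps_to_zero(self):
        assert ev.expected_pw_from_sh(0.0, 40) == 0.0
        assert ev.expected_loo_from_sh(0.0, 40) == 0.0

    def test_noise_free_limit(self):
        assert ev.expected_pw_from_sh(0.999999, 4) == pytest.approx(1.0, abs=1e-4)
        assert ev.expected_loo_from_sh(0.999999, 4) == pytest.approx(1.0, abs=1e-4)

    def test_round_trip_with_generating_r(self):
        # sh = m r / (1+(m-1)r) at r=0.2, n=40 inverts back to r and the
        # closed-form looISC
        sh = 20 * 0.2 / (1 + 19 * 0.2)
        assert ev.expected_pw_from_sh(sh, 40) == pytest.approx(0.2, abs=1e-12)
        loo = 0.2 * np.sqrt(39 / (1 + 38 * 0.2))
        assert ev.expected_loo_from_sh(sh, 40) == pytest.approx(loo, abs=1e-12)

    def test_inconsistent_input_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ev.expected_pw_from_sh(1.5, 6)  # sh >= m/(m-1) = 1.5 at m=3
        with pytest.raises(ValueError):
            ev.expected_pw_from_sh(0.5, 5)  # odd n


class TestLeaveOneOut:
    def test_identical_subjects(self):
        cohort, _ = _shared_signal_cohort(noise_sd=0.0)
        np.testing.assert_allclose(ev.loo_isc(cohort), 1.0, atol=1e-12)

    def test_outlier_subject_near_zero(self):
        cohort, sig = _shared_signal_cohort(n=6, P=1, T=500, noise_sd=0.3, seed=2)
        rng = np.random.default_rng(3)
        outlier = Subject("X", 10.0, "M", "A", rng.standard_normal((1, 500)))
        cohort = CohortDataset(cohort.subjects + [outlier], tr=0.8)
        loo = ev.loo_isc(cohort)
        assert abs(loo[-1, 0]) < 0.15
        assert np.all(loo[:-1, 0] > 0.8)

    def test_mean_matches_closed_form(self):
        vals = [
            ev.loo_isc(_shared_signal_cohort(n=40, P=1, T=750, noise_sd=2.0, seed=s)[0]).mean()
            for s in range(10)
        ]
        expect = 0.2 * np.sqrt(39 / (1 + 38 * 0.2))  # ~0.426
        assert abs(np.mean(vals) - expect) < 0.03


class TestIscB:
    def test_same_population_near_one(self, small_cohort):
        rng = np.random.default_rng(0)
        sig = zscore(rng.standard_normal((2, 400)), axis=-1)
        a = _cohort_from_stack([sig + rng.standard_normal((2, 400)) for _ in range(20)], "A")
        b = _cohort_from_stack([sig + rng.standard_normal((2, 400)) for _ in range(20)], "B")
        vals = np.nanmean([ev.isc_b(a, b, seed=s) for s in range(5)], axis=0)
        np.testing.assert_allclose(vals, 1.0, atol=0.1)

    def test_orthogonal_signals_near_zero(self):
        rng = np.random.default_rng(1)
        sig_a = zscore(rng.standard_normal((1, 750)), axis=-1)
        sig_b = zscore(rng.standard_normal((1, 750)), axis=-1)
        a = _cohort_from_stack([sig_a + 0.5 * rng.standard_normal((1, 750)) for _ in range(20)], "A")
        b = _cohort_from_stack([sig_b + 0.5 * rng.standard_normal((1, 750)) for _ in range(20)], "B")
        vals = np.nanmean([ev.isc_b(a, b, seed=s) for s in range(5)], axis=0)
        assert abs(vals[0]) < 0.1

    def test_symmetry_under_swap_with_seed_pair(self, small_cohort):
        cohort, _ = small_cohort
        groups = cohort.groups()
        ab = ev.isc_b(groups["A"], groups["B"], seed=(11, 22))
        ba = ev.isc_b(groups["B"], groups["A"], seed=(22, 11))
        np.testing.assert_allclose(ab, ba, atol=1e-12)

    def test_nonpositive_within_term_is_missing(self):
        x = zscore(np.random.default_rng(2).standard_normal((1, 100)), axis=-1)
        # anticorrelated pairs: every equal split has within-group r <= 0 or a
        # constant half-mean, so the statistic is undefined
        b = _cohort_from_stack([x, -x, 2 * x, -2 * x], "B")
        a, _ = _shared_signal_cohort(n=4, P=1, T=100, noise_sd=0.1, seed=3)
        for s in range(5):
            assert np.isnan(ev.isc_b(a, b, seed=s)[0])


class TestCovariate:
    def test_self_correlation_is_one(self):
        loo = np.linspace(0.1, 0.5, 20)
        r, p = ev.covariate_vs_isc(loo, loo)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ev.covariate_vs_isc(np.arange(5.0), np.ones(5))

    def test_attenuation_with_equal_noise(self):
        # covariate = looISC + independent noise of equal variance -> E r ~ 1/sqrt(2)
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(50):
            loo = rng.standard_normal(200)
            cov = loo + rng.standard_normal(200)
            rs.append(ev.covariate_vs_isc(loo, cov)[0])
        assert abs(np.mean(rs) - 1 / np.sqrt(2)) < 0.03


class TestSubsampleAverage:
    def test_constant_statistic(self, small_cohort):
        cohort, _ = small_cohort
        mean, draws = ev.subsample_average(lambda ds, s: 0.7, cohort, n_subsamples=5)
        assert mean == pytest.approx(0.7)
        assert draws.shape == (5,)

    def test_arithmetic_mean(self, small_cohort):
        cohort, _ = small_cohort
        vals = iter([0.1, 0.2, 0.3, 0.4, 0.5])
        mean, _ = ev.subsample_average(lambda ds, s: next(vals), cohort, n_subsamples=5)
        assert mean == pytest.approx(0.3)

    def test_averaging_reduces_variance(self, small_cohort):
        cohort, _ = small_cohort
        group = cohort.groups()["A"]
        single = [ev.split_half_isc(group, seed=s)[0] for s in range(40)]
        averaged = [
            ev.subsample_average(
                lambda ds, s: ev.split_half_isc(ds, s)[0], group,
                n_subsamples=5, seeds=list(range(5 * k, 5 * k + 5)),
            )[0]
            for k in range(8)
        ]
        assert np.var(averaged) < np.var(single)
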
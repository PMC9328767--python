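"""Synthetic generator: determinism, calibration, and construction contracts."""

import numpy as np
import pytest

import eventisc as ev
from eventisc._utils import zscore
from eventisc.synth import event_labels

from conftest import rand_bounds


class TestEventPatterns:
    def test_zscored_and_deterministic(self):
        a = ev.make_event_patterns(4, 30, seed=3)
        b = ev.make_event_patterns(4, 30, seed=3)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(a.std(axis=1), 1, atol=1e-12)
        assert not np.allclose(a, ev.make_event_patterns(4, 30, seed=4))

    def test_near_orthogonal_at_high_dim(self):
        # mean absolute off-diagonal correlation stays small for V >> K
        vals = []
        for seed in range(100):
            p = ev.make_event_patterns(5, 50, seed=seed)
            c = np.corrcoef(p)
            vals.append(np.abs(c[np.triu_indices(5, 1)]).mean())
        assert np.mean(vals) < 0.3

    def test_orthogonal_infeasible(self):
        with pytest.raises(ValueError, match="orthogonalize"):
            ev.make_event_patterns(10, 4, seed=0, orthogonal=True)


class TestGroupSignal:
    def test_piecewise_constant(self):
        pats = ev.make_event_patterns(2, 5, seed=0)
        sig = ev.make_group_signal(pats, [5], 10)
        np.testing.assert_array_equal(sig[:, :5], np.tile(pats[0][:, None], 5))
        np.testing.assert_array_equal(sig[:, 5:], np.tile(pats[1][:, None], 5))

    def test_empty_boundaries_constant(self):
        pats = ev.make_event_patterns(2, 5, seed=0)
        sig = ev.make_group_signal(pats, [], 8)
        assert np.ptp(sig, axis=1).max() == 0

    def test_event_label_counting(self):
        np.testing.assert_array_equal(
            event_labels([3, 7], 12), [1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3]
        )


class TestCorrelatedSignal:
    def test_rho_one_is_zscored_copy(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((3, 100))
        b = ev.make_correlated_group_signal(a, 1.0, seed=1)
        np.testing.assert_allclose(b, zscore(a, axis=-1), atol=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_sample_correlation_converges(self, rho):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((1, 10000))
        b = ev.make_correlated_group_signal(a, rho, seed=3)
        r = np.corrcoef(a[0], b[0])[0, 1]
        assert abs(r - rho) < 0.05  # Fisher-z 95% half-width at n=1e4 is ~0.02


class TestSubjects:
    def test_zero_noise_identical(self):
        sig = np.arange(12.0).reshape(3, 4)
        subs = ev.make_subjects(sig, 3, 0.0, seed=0)
        for s in subs:
            np.testing.assert_array_equal(s, sig)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ev.make_subjects(np.zeros((2, 5)), 2, -1.0, seed=0)

    def test_pairwise_correlation_calibration(self):
        # unit-variance signal + noise_sd=2 -> expected pairwise r = 1/(1+4)
        rng = np.random.default_rng(5)
        means = []
        for rep in range(20):
            sig = zscore(rng.standard_normal((1, 750)), axis=-1)
            subs = np.stack(ev.make_subjects(sig, 40, 2.0, seed=rep))[:, 0, :]
            c = np.corrcoef(subs)
            means.append(c[np.triu_indices(40, 1)].mean())
        assert abs(np.mean(means) - 0.2) < 0.02


class TestAnnotations:
    def test_exact_when_noiseless(self):
        true_b = np.array([10.0, 50.0, 90.0])
        ann = ev.make_annotations(true_b, 5, 0.0, 0.0, seed=0, duration_s=100)
        for r in ann.raters:
            np.testing.assert_array_equal(r.boundaries_s, true_b)

    def test_miss_rate_expectation(self):
        true_b = np.linspace(10, 580, 12)
        ann = ev.make_annotations(true_b, 21, 0.5, 0.2, seed=1, duration_s=600)
        counts = [len(r.boundaries_s) for r in ann.raters]
        assert abs(np.mean(counts) - 12 * 0.8) < 1.0
        for r in ann.raters:
            assert np.all(np.diff(r.boundaries_s) >= 0)


class TestBoundaryLockedRoi:
    def test_infeasible_slope_rejected(self):
        with pytest.raises(ValueError, match="negative gains"):
            ev.make_boundary_locked_roi(
                np.array([5.0, 19.0]), np.ones(10), 0.1, -0.2, 1.0, seed=0
            )

    def test_noiseless_correlations_saturate(self):
        # correlation is scale-invariant: without noise every subject's
        # boundary correlation is 1 regardless of gain
        btc = np.sin(np.linspace(0, 6 * np.pi, 200)) + 2
        ages = np.linspace(5, 19, 20)
        roi = ev.make_boundary_locked_roi(ages, btc, 1.0, -0.02, 0.0, seed=0)
        rs = [np.corrcoef(tc, btc)[0, 1] for tc in roi]
        np.testing.assert_allclose(rs, 1.0, atol=1e-10)

    def test_negative_slope_gives_negative_age_effect(self):
        btc = np.sin(np.linspace(0, 6 * np.pi, 400)) + 2
        rng = np.random.default_rng(4)
        ages = rng.uniform(5, 19, 300)
        roi = ev.make_boundary_locked_roi(ages, btc, 1.0, -0.02, 5.0, seed=5)
        rs = [np.corrcoef(tc, btc)[0, 1] for tc in roi]
        r, _ = ev.age_effect(rs, ages)
        assert r < -0.2


class TestCohort:
    def test_determinism(self):
        spec = ev.SimSpec(n_parcels=2, n_timepoints=100, n_subjects_per_group=4,
                          n_male_per_group=2, boundaries_tr=(30, 60), seed=9)
        c1, t1 = ev.make_cohort(spec)
        c2, t2 = ev.make_cohort(spec)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            np.testing.assert_array_equal(s1.data, s2.data)
            assert (s1.age, s1.gender, s1.group) == (s2.age, s2.gender, s2.group)
        np.testing.assert_array_equal(t1.group_signals["B"], t2.group_signals["B"])

    def test_gender_counts_and_shifted_boundaries(self):
        spec = ev.SimSpec(n_parcels=1, n_timepoints=200, n_subjects_per_group=10,
                          n_male_per_group=6, boundaries_tr=(50, 100, 150),
                          shift_tr=5, seed=2)
        cohort, truth = ev.make_cohort(spec)
        meta = cohort.metadata()
        for g in ("A", "B"):
            assert ((meta["group"] == g) & (meta["gender"] == "M")).sum() == 6
        np.testing.assert_array_equal(
            truth.true_boundaries_tr["B"], np.array([45, 95, 145])
        )

    def test_shift_fidelity_noise_free(self):
        # cross-correlation between the group mean signals peaks at shift_tr
        spec = ev.SimSpec(n_parcels=1, n_features=20, n_timepoints=300,
                          n_subjects_per_group=4, n_male_per_group=2,
                          noise_sd=0.0, rho_b=1.0, shift_tr=7,
                          boundaries_tr=tuple(rand_bounds(np.random.default_rng(1), 8, 300)),
                          seed=11)
        _, truth = ev.make_cohort(spec)
        a = truth.group_signals["A"][0]
        b = truth.group_signals["B"][0]
        # positive lag l pairs b[t] with a[t+l]; B leads A by shift_tr, so
        # b[t] = a[t + shift] and the peak sits at l = +7
        lags = np.arange(-15, 16)
        xc = []
        for l in lags:
            if l >= 0:
                pairs = (b[:, : 300 - l], a[:, l:])
            else:
                pairs = (b[:, -l:], a[:, : 300 + l])
            xc.append(np.mean([np.corrcoef(x, y)[0, 1] for x, y in zip(*pairs)]))
        assert lags[int(np.argmax(xc))] == 7
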
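"""Ordered-event HMM: posterior correctness, EM behavior, selection, joint fit."""

import numpy as np
import pytest

import eventisc as ev
from eventisc import hmm as H
from eventisc._utils import zscore

from conftest import brute_force_posterior, structured_subjects, zscored_average


class TestPosterior:
    @pytest.mark.parametrize("T,K,V", [(8, 2, 3), (10, 3, 4), (12, 3, 2)])
    def test_matches_brute_force_enumeration(self, T, K, V):
        rng = np.random.default_rng(T + K)
        data = zscore(rng.standard_normal((V, T)), axis=-1)
        patterns = rng.standard_normal((K, V))
        var = 0.7
        expect_gamma, expect_ll = brute_force_posterior(data, patterns, var, K)
        gamma, ll = H._posterior(H._log_emissions(data, patterns, var), K)
        np.testing.assert_allclose(gamma, expect_gamma, atol=1e-10)
        assert ll == pytest.approx(expect_ll, abs=1e-10)

    def test_rows_sum_to_one_and_expected_index_monotone(self):
        subs, _, _ = structured_subjects(seed=0)
        _, gamma = ev.fit_hmm(zscored_average(subs), 7)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        expected_index = gamma @ np.arange(1, 8)
        assert np.all(np.diff(expected_index) >= -1e-9)


class TestFit:
    def test_noiseless_exact_boundary_recovery(self):
        pats = ev.make_event_patterns(5, 20, seed=0)
        true_b = [10, 25, 40, 70]
        sig = zscore(ev.make_group_signal(pats, true_b, 100), axis=-1)
        _, gamma = ev.fit_hmm(sig, 5)
        np.testing.assert_array_equal(ev.recovered_boundaries(gamma), true_b)

    def test_em_loglik_monotone(self):
        subs, _, _ = structured_subjects(seed=1, noise_sd=1.0)
        trace = H.em_loglik_trace(zscored_average(subs), 7, max_iter=30)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_pattern_order_recovery(self):
        subs, b, pats = structured_subjects(seed=2, noise_sd=0.5)
        model, _ = ev.fit_hmm(zscored_average(subs), 7)
        # each recovered pattern correlates maximally with the generating
        # pattern of the same ordinal position
        c = np.corrcoef(model.patterns, pats)[:7, 7:]
        np.testing.assert_array_equal(np.argmax(c, axis=1), np.arange(7))

    def test_invalid_inputs_rejected(self):
        data = np.zeros((3, 10))
        with pytest.raises(ValueError):
            ev.fit_hmm(data, 11)  # K > T
        bad = data.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            ev.fit_hmm(bad, 2)

    def test_repeated_pattern_degenerate_case(self):
        # one pattern throughout: boundary placement arbitrary, but gamma
        # stays a proper posterior
        rng = np.random.default_rng(3)
        sig = zscore(np.tile(rng.standard_normal((10, 1)), (1, 60))
                     + 0.01 * rng.standard_normal((10, 60)), axis=-1)
        _, gamma = ev.fit_hmm(sig, 2)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestHeldOut:
    def test_identical_data_reproduces_training_loglik(self):
        subs, _, _ = structured_subjects(seed=4)
        avg = zscored_average(subs)
        model, _ = ev.fit_hmm(avg, 7)
        assert ev.held_out_loglik(model, avg) == pytest.approx(model.train_loglik, abs=1e-9)

    def test_ordering_structured_vs_noise_and_shuffled(self):
        subs, _, _ = structured_subjects(seed=5)
        avg = zscored_average(subs)
        model, _ = ev.fit_hmm(avg, 7)
        rng = np.random.default_rng(6)
        noise = zscore(rng.standard_normal(avg.shape), axis=-1)
        shuffled = avg[:, rng.permutation(avg.shape[1])]
        ll_struct = ev.held_out_loglik(model, avg)
        assert ll_struct > ev.held_out_loglik(model, shuffled)
        assert ll_struct > ev.held_out_loglik(model, noise)

    def test_dimension_mismatch_rejected(self):
        subs, _, _ = structured_subjects(seed=7)
        model, _ = ev.fit_hmm(zscored_average(subs), 7)
        with pytest.raises(ValueError):
            ev.held_out_loglik(model, np.zeros((5, 300)))


class TestSelection:
    def test_default_grid_endpoints(self):
        assert H.DEFAULT_K_GRID[0] == 2
        assert H.DEFAULT_K_GRID[-1] == 50

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValueError):
            ev.select_k([np.zeros((4, 50))] * 3, n_folds=5)

    def test_recovers_true_k_when_strongly_structured(self):
        subs, _, _ = structured_subjects(seed=8, K=8, noise_sd=0.1)
        k = ev.select_k(subs, K_grid=(2, 3, 4, 5, 6, 8, 10, 13), seed=0)
        assert k == 8.0

    def test_structureless_noise_selects_minimum(self):
        rng = np.random.default_rng(9)
        noise = [rng.standard_normal((10, 100)) for _ in range(5)]
        grid = (2, 3, 4, 6, 8)
        k = ev.select_k(noise, K_grid=grid, seed=0)
        idx = ev.event_structure_index(noise, K_grid=grid, seed=0)
        assert k <= 3.0
        assert idx < H.DEFAULT_STRUCTURE_THRESHOLD

    def test_structured_index_exceeds_threshold(self):
        subs, _, _ = structured_subjects(seed=10, K=8, noise_sd=0.5)
        idx = ev.event_structure_index(subs, K_grid=(2, 3, 4, 5, 6, 8, 10), seed=0)
        assert idx > H.DEFAULT_STRUCTURE_THRESHOLD

    def test_snap_to_grid(self):
        assert ev.snap_to_grid(7.2) == 8
        assert ev.snap_to_grid(2.0) == 2
        assert ev.snap_to_grid(44.0) == 40


class TestJointFit:
    def test_identical_groups_symmetric(self):
        subs, _, _ = structured_subjects(seed=11, K=5, V=20, T=150, n=5)
        fit = ev.joint_fit(subs, [s.copy() for s in subs], 5, seed=0)
        np.testing.assert_allclose(fit.gamma["A"], fit.gamma["B"], atol=1e-9)
        assert fit.heldout_loglik["A"] == pytest.approx(fit.heldout_loglik["B"], abs=1e-9)

    def test_shifted_group_leads_in_gamma(self):
        spec = ev.SimSpec(n_parcels=1, n_features=30, n_timepoints=200,
                          n_subjects_per_group=5, n_male_per_group=2,
                          noise_sd=0.5, shift_tr=5,
                          boundaries_tr=(40, 80, 120, 160), seed=12)
        cohort, _ = ev.make_cohort(spec)
        gs = cohort.groups()
        fit = ev.joint_fit([s.pvt[0] for s in gs["A"].subjects],
                           [s.pvt[0] for s in gs["B"].subjects], 5, seed=0)
        # group B (earlier boundaries) spends more time in later events
        assert ev.anticipation_score(fit.gamma["B"]) > ev.anticipation_score(fit.gamma["A"])


class TestBoundaryTimecourse:
    def test_hard_switch_impulse(self, clean_gamma):
        tc = ev.boundary_timecourse_from_gamma(clean_gamma)
        expect = np.zeros(12)
        expect[4] = 1.0
        expect[9] = 1.0
        np.testing.assert_array_equal(tc, expect)

    def test_constant_gamma_all_zero(self):
        gamma = np.full((10, 4), 0.25)
        np.testing.assert_array_equal(ev.boundary_timecourse_from_gamma(gamma), np.zeros(10))

    def test_telescoping_sum_bounded(self):
        subs, _, _ = structured_subjects(seed=13, K=6, V=20, T=150)
        _, gamma = ev.fit_hmm(zscored_average(subs), 6)
        tc = ev.boundary_timecourse_from_gamma(gamma)
        assert tc.sum() <= 6 - 1 + 1e-9
        assert np.all(tc >= 0)
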
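"""Fold schemes, the decoding loop, metrics and the significance rule."""

import numpy as np
import pytest

from patternreg import (FoldScheme, GeneratorConfig, decide_significance,
                        generate_dataset, make_kfold, make_loo, mse,
                        pearson_r, run_decoding)

from conftest import small_config


class TestMakeLoo:
    def test_three_singletons(self):
        scheme = make_loo(3)
        assert [list(f) for f in scheme.folds] == [[0], [1], [2]]

    def test_study_size_yields_n_folds(self):
        scheme = make_loo(57)
        assert len(scheme.folds) == 57
        assert all(len(f) == 1 for f in scheme.folds)

    def test_partition_property(self):
        scheme = make_loo(11)
        all_idx = np.sort(np.concatenate(scheme.folds))
        np.testing.assert_array_equal(all_idx, np.arange(11))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_loo(2)


class TestMakeKfold:
    def test_57_into_4_gives_15_14_14_14(self, rng):
        scores = rng.normal(15.5, 6.3, size=57)
        scheme = make_kfold(scores, 4, seed=0)
        sizes = sorted(len(f) for f in scheme.folds)
        assert sizes == [14, 14, 14, 15]

    def test_equal_scores_accepted_first_attempt(self):
        scheme = make_kfold(np.full(8, 3.0), 4, seed=5)
        assert scheme.attempts_used == 1
        np.testing.assert_allclose(scheme.balance_pvalues, 1.0)

    def test_accepted_partition_is_balanced(self, rng):
        scores = rng.normal(size=40)
        scheme = make_kfold(scores, 5, seed=3)
        assert np.all(scheme.balance_pvalues > 0.05)

    def test_balance_pvalues_replay(self, rng):
        # postcondition replay with the scipy t-test
        from scipy import stats
        scores = rng.normal(size=30)
        scheme = make_kfold(scores, 3, seed=1)
        for f, p in zip(scheme.folds, scheme.balance_pvalues):
            rest = np.setdiff1d(np.arange(30), f)
            _, p_ref = stats.ttest_ind(scores[f], scores[rest],
                                       equal_var=True)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        scores = rng.normal(size=24)
        s1 = make_kfold(scores, 4, seed=9)
        s2 = make_kfold(scores, 4, seed=9)
        for f1, f2 in zip(s1.folds, s2.folds):
            np.testing.assert_array_equal(f1, f2)

    def test_argument_validation(self, rng):
        scores = rng.normal(size=10)
        with pytest.raises(ValueError):
            make_kfold(scores, 1)
        with pytest.raises(ValueError):
            make_kfold(scores, 6)

    def test_unbalanceable_scores_raise(self):
        # deterministic adversarial labels: any near-equal split of these
        # extreme groups still differs; the error names the worst p-value
        scores = np.array([0.0] * 7 + [1e6])
        with pytest.raises(RuntimeError, match="p-value"):
            make_kfold(scores, 2, seed=0, alpha_balance=0.9,
                       max_attempts=5)


class TestMetrics:
    def test_perfect_and_anti_correlation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_hand_value(self):
        # r([1,2,3],[1,2,4]) = 9 / sqrt(84)
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(
            9 / np.sqrt(84))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_mse_cases(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse([0.0, 0.0], [1.0, 3.0]) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])

    def test_mse_nonnegative_random(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mse(a, b) >= 0


class TestDecideSignificance:
    @pytest.mark.parametrize("p_r, p_mse, expected", [
        (0.001, 0.001, True),    # both clearly significant
        (0.14, 0.07, False),     # neither below threshold
        (0.049, 0.051, False),   # strict AND at the boundary
        (0.051, 0.049, False),
        (0.049, 0.049, True),
    ])
    def test_joint_rule(self, p_r, p_mse, expected):
        assert decide_significance(p_r, p_mse, 0.05) is expected

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            decide_significance(-0.1, 0.5)


class TestRunDecoding:
    def test_noiseless_recovery(self):
        # unclipped linear score so the noiseless limit is exactly linear
        cfg = small_config(grid_shape=(5, 5, 4), n_subjects=40, n_blobs=1,
                          noise_sd=0.0, seed=30, score_model="custom",
                          score_loc=15.5, score_scale=6.3,
                          score_bounds=(-100.0, 130.0))
        ds, _ = generate_dataset(cfg)
        res = run_decoding(ds, make_loo(40))
        assert res.r > 0.99

    def test_scheme_equivalence_loo_vs_nfold(self):
        cfg = small_config(n_subjects=14, noise_sd=0.4, seed=8)
        ds, _ = generate_dataset(cfg)
        loo = run_decoding(ds, make_loo(14))
        nfold = FoldScheme(kind="kfold",
                           folds=[np.array([i]) for i in range(14)], k=14)
        kres = run_decoding(ds, nfold)
        np.testing.assert_allclose(loo.y_pred, kres.y_pred, atol=1e-10)

    def test_null_scores_give_weak_correlation(self):
        cfg = small_config(grid_shape=(5, 5, 2), n_subjects=40, n_blobs=0,
                          noise_sd=1.0, seed=77)
        ds, _ = generate_dataset(cfg)
        res = run_decoding(ds, make_loo(40))
        assert abs(res.r) < 0.3

    def test_no_leakage_from_test_rows(self):
        # everything fitted for a fold (centering, confound coefficients,
        # kernel) must derive from training rows only: corrupting the
        # held-out subject's features leaves that fold's training state
        # bit-identical
        from patternreg.crossval import prepare_folds
        cfg = small_config(n_subjects=12, seed=14)
        ds, _ = generate_dataset(cfg)
        scheme = make_loo(12)
        clean = prepare_folds(ds.X, ds.confound, scheme,
                              control_confound=True)
        X2 = ds.X.copy()
        X2[4] += 1e6
        dirty = prepare_folds(X2, ds.confound, scheme,
                              control_confound=True)
        f_clean = next(f for f in clean if f.test_idx[0] == 4)
        f_dirty = next(f for f in dirty if f.test_idx[0] == 4)
        np.testing.assert_array_equal(f_clean.K_train, f_dirty.K_train)
        np.testing.assert_array_equal(f_clean.Xc_train, f_dirty.Xc_train)
        # the held-out subject enters only through the cross kernel
        assert not np.allclose(f_clean.K_cross, f_dirty.K_cross)

    def test_weight_map_unit_norm_and_sign(self):
        cfg = small_config(n_subjects=30, n_blobs=1, noise_sd=0.1, seed=44,
                          blob_centers=((3, 3, 1),), blob_signs=(1.0,))
        ds, truth = generate_dataset(cfg)
        res = run_decoding(ds, make_loo(30))
        assert np.linalg.norm(res.weight_map) == pytest.approx(1.0,
                                                               abs=1e-10)
        w_true = ds.mask.extract(truth.weight_volume)
        assert np.corrcoef(res.weight_map, w_true)[0, 1] > 0

    def test_pooled_predictions_out_of_fold(self):
        cfg = small_config(n_subjects=12, seed=6)
        ds, _ = generate_dataset(cfg)
        res = run_decoding(ds, make_loo(12))
        assert res.y_pred.shape == (12,)
        assert np.all(np.isfinite(res.y_pred))
        np.testing.assert_array_equal(res.y_true, ds.scores)

    def test_confound_single_class_in_fold_names_fold(self):
        cfg = small_config(n_subjects=10, seed=3)
        ds, _ = generate_dataset(cfg)
        ds.confound[:] = 0
        ds.confound[0] = 1  # removing subject 0 leaves one class
        with pytest.raises(ValueError, match="fold 0"):
            run_decoding(ds, make_loo(10), control_confound=True)

    def test_tiny_fold_rejected(self):
        cfg = small_config(n_subjects=3, seed=1)
        ds, _ = generate_dataset(cfg)
        with pytest.raises(ValueError, match="fewer than 3"):
            run_decoding(ds, make_loo(3))

    def test_confound_control_on_contaminated_data(self):
        # confound drives its own spatial pattern; with no score-confound
        # association, residualization must not destroy decoding
        cfg = small_config(grid_shape=(6, 6, 4), n_subjects=60, n_blobs=1,
                          noise_sd=0.2, confound_pattern_gain=2.0,
                          confound_score_shift=0.0, seed=22)
        ds, _ = generate_dataset(cfg)
        plain = run_decoding(ds, make_loo(60))
        controlled = run_decoding(ds, make_loo(60), control_confound=True)
        assert controlled.r > plain.r - 0.1
        assert controlled.r > 0.8
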
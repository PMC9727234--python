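import numpy as np
import pytest

from wmcov.prediction import (
    PatternMatrix,
    PredictionConfig,
    cohens_d,
    fit_predict_svr,
    permutation_pvalue,
    predictive_pattern,
    repeated_cv,
    select_features,
    split_half_transfer,
)


class TestConfig:
    def test_defaults(self):
        cfg = PredictionConfig()
        assert cfg.k_folds == 10 and cfg.n_repeats == 1000
        assert cfg.selection_alpha == 0.05
        assert cfg.svr_cost == 1.0 and cfg.svr_epsilon == 0.1

    @pytest.mark.parametrize(
        "kwargs", [{"k_folds": 1}, {"n_repeats": 0}, {"selection_alpha": 1.0}]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            PredictionConfig(**kwargs)


class TestSelectFeatures:
    def test_score_column_selected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 10))
        y = X[:, 4].copy()
        sel = select_features(X, y)
        assert 4 in sel

    def test_alpha_one_selects_all_nonconstant(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 8))
        X[:, 2] = 5.0  # constant column excluded with a warning, not an error
        sel = select_features(X, rng.standard_normal(30), alpha=1.0)
        assert sorted(sel) == [0, 1, 3, 4, 5, 6, 7]

    def test_null_selection_rate_near_alpha(self):
        # 200 null simulations, n=100, E=66: mean selected fraction ~ alpha
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(200):
            X = rng.standard_normal((100, 66))
            y = rng.standard_normal(100)
            fracs.append(len(select_features(X, y, 0.05)) / 66)
        assert 0.03 < np.mean(fracs) < 0.07

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="10"):
            select_features(np.zeros((5, 3)), np.zeros(5))


class TestFitPredictSvr:
    def test_constant_target(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        pred = fit_predict_svr(X, np.full(20, 7.0), X[:5])
        assert np.allclose(pred, 7.0)

    def test_perfect_linear_signal(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        X = x[:, None]
        pred = fit_predict_svr(X[:150], x[:150], X[150:])
        assert np.corrcoef(pred, x[150:])[0, 1] > 0.95

    def test_empty_selection_predicts_training_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        pred = fit_predict_svr(np.zeros((3, 0)), y, np.zeros((4, 0)))
        assert np.allclose(pred, 2.0)

    def test_duplicated_feature_gamma_dependence(self):
        # duplicating the single feature halves gamma; after accounting for
        # the doubled squared distance the rbf kernel is unchanged, so
        # predictions agree exactly.
        rng = np.random.default_rng(2)
        x = rng.standard_normal(80)
        y = x + 0.1 * rng.standard_normal(80)
        X1 = x[:, None]
        X2 = np.column_stack([x, x])
        p1 = fit_predict_svr(X1[:60], y[:60], X1[60:])
        p2 = fit_predict_svr(X2[:60], y[:60], X2[60:])
        assert np.allclose(p1, p2, atol=1e-8)

    def test_missing_values_rejected(self):
        X = np.ones((12, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_predict_svr(X, np.ones(12), X)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        p1 = fit_predict_svr(X, y, X[:10])
        p2 = fit_predict_svr(X, y, X[:10])
        assert np.array_equal(p1, p2)


class TestPermutationPvalue:
    def test_identity_predictions_minimal_p(self):
        y = np.arange(50, dtype=float)
        assert permutation_pvalue(y, y, 999, seed=0) == pytest.approx(1 / 1000)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(40)
        pred = y + rng.standard_normal(40)
        p1 = permutation_pvalue(y, pred, 500, seed=7)
        p2 = permutation_pvalue(y, -pred, 500, seed=7)
        assert p1 == p2

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            y = rng.standard_normal(30)
            pred = rng.standard_normal(30)
            if permutation_pvalue(y, pred, 199, seed=int(rng.integers(2**31))) < 0.05:
                hits += 1
        assert 0.03 < hits / n_sim < 0.07

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            permutation_pvalue(np.ones(20), np.arange(20.0), 99, 0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        y, pred = rng.standard_normal(25), rng.standard_normal(25)
        assert permutation_pvalue(y, pred, 299, 11) == permutation_pvalue(
            y, pred, 299, 11
        )


def _signal_table(n=120, e=20, rho=0.9, noise=0.3, seed=0):
    """Direct synthetic edge table: one informative edge column."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    X = rng.standard_normal((n, e)) * 0.3
    X[:, 5] += z
    y = rho * z + rng.normal(0, noise, n)
    return X, y


class TestRepeatedCv:
    def test_signal_recovered(self):
        X, y = _signal_table()
        cfg = PredictionConfig(n_repeats=10, n_permutations=499, seed=1)
        perf = repeated_cv(X, y, cfg)
        assert perf.r_mean > 0.3
        assert perf.permutation_p < 0.01
        assert perf.n_subjects_used == 120
        assert len(perf.per_repeat_r) == 10

    def test_null_r_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 15))
        y = rng.standard_normal(60)
        perf = repeated_cv(X, y, PredictionConfig(n_repeats=10, seed=2))
        assert abs(perf.r_mean) < 0.35

    def test_determinism(self):
        X, y = _signal_table(n=60, e=10)
        cfg = PredictionConfig(n_repeats=5, n_permutations=99, seed=9)
        p1 = repeated_cv(X, y, cfg)
        p2 = repeated_cv(X, y, cfg)
        assert p1.r_mean == p2.r_mean
        assert p1.mae_mean == p2.mae_mean
        assert p1.permutation_p == p2.permutation_p
        assert np.array_equal(p1.per_repeat_r, p2.per_repeat_r)

    def test_missing_scores_dropped(self):
        X, y = _signal_table(n=80, e=10)
        y2 = y.copy()
        y2[:10] = np.nan
        perf = repeated_cv(X, y2, PredictionConfig(n_repeats=3, seed=0))
        assert perf.n_subjects_used == 70

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="30"):
            repeated_cv(np.zeros((20, 5)), np.zeros(20), PredictionConfig(n_repeats=1))

    def test_no_leakage_from_heldout_scores(self):
        # corrupting one subject's score changes only folds where that
        # subject is in TRAINING; when it is held out, the fold's model and
        # therefore its predictions for other held-out subjects are identical.
        from wmcov.prediction import _kfold_indices, _one_repeat

        X, y = _signal_table(n=50, e=10, seed=3)
        cfg = PredictionConfig(n_repeats=1, seed=4)
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        folds = _kfold_indices(50, cfg.k_folds, np.random.default_rng(0))
        victim = folds[0][0]  # subject held out in fold 0
        y_corrupt = y.copy()
        y_corrupt[victim] += 1000.0
        pred_clean = _one_repeat(X, y, cfg, rng1)
        pred_corrupt = _one_repeat(X, y_corrupt, cfg, rng2)
        mates = np.setdiff1d(folds[0], [victim])
        assert np.array_equal(pred_clean[mates], pred_corrupt[mates])

    def test_r_mean_converges_across_seed_blocks(self):
        X, y = _signal_table(n=80, e=10, seed=6)
        small = [
            repeated_cv(X, y, PredictionConfig(n_repeats=2, seed=s)).r_mean
            for s in range(4)
        ]
        large = [
            repeated_cv(X, y, PredictionConfig(n_repeats=10, seed=s)).r_mean
            for s in range(4)
        ]
        assert np.std(large) <= np.std(small) + 0.02


class TestSplitHalf:
    def test_shared_coupling_transfers_both_ways(self):
        rng = np.random.default_rng(0)
        n = 120
        z = rng.standard_normal(n)
        X = rng.standard_normal((n, 15)) * 0.3
        X[:, 4] += z
        y = 0.9 * z + rng.normal(0, 0.2, n)
        ages = rng.uniform(20, 89, n)
        cfg = PredictionConfig(n_permutations=199, seed=1)
        y2o, o2y = split_half_transfer(X, y, ages, cfg)
        assert y2o.r_mean > 0 and o2y.r_mean > 0

    def test_signal_only_in_training_half_gives_null_test(self):
        rng = np.random.default_rng(1)
        n = 120
        ages = np.r_[rng.uniform(20, 50, 60), rng.uniform(60, 89, 60)]
        z = rng.standard_normal(n)
        X = rng.standard_normal((n, 15)) * 0.3
        young = ages <= ages.mean()
        X[young, 4] += z[young]  # coupling exists only in the young half
        y = np.where(young, 0.9 * z, rng.standard_normal(n) * 0.9)
        y += rng.normal(0, 0.2, n)
        cfg = PredictionConfig(n_permutations=199, seed=2)
        y2o, _ = split_half_transfer(X, y, ages, cfg)
        assert abs(y2o.r_mean) < 0.3

    def test_mean_age_tie_goes_to_younger_group(self):
        rng = np.random.default_rng(2)
        n = 40
        ages = np.full(n, 50.0)
        ages[: n // 2] = 30.0
        ages[n // 2 :] = 70.0
        # insert ties exactly at the mean (50.0)
        ages[0] = 50.0
        ages[-1] = 50.0
        X = rng.standard_normal((n, 5))
        y = X[:, 0] + rng.normal(0, 0.1, n)
        cfg = PredictionConfig(n_permutations=99, seed=3)
        y2o, o2y = split_half_transfer(X, y, ages, cfg)
        # young = age <= mean: 19 thirty-year-olds + 2 at the mean = 21
        assert o2y.n_subjects_used == 21
        assert y2o.n_subjects_used == 19

    def test_group_too_small(self):
        rng = np.random.default_rng(3)
        ages = np.r_[np.full(5, 20.0), np.full(40, 80.0)]
        X = rng.standard_normal((45, 5))
        y = rng.standard_normal(45)
        with pytest.raises(ValueError, match="15"):
            split_half_transfer(X, y, ages, PredictionConfig(seed=0))


class TestPredictivePattern:
    def test_exact_edge_recovered_with_sign(self):
        rng = np.random.default_rng(0)
        n_regions = 6
        E = n_regions * (n_regions - 1) // 2
        X = rng.standard_normal((50, E))
        y = -X[:, 3].copy()  # edge (1,5) in row-major upper triangle of R=6
        pm = predictive_pattern(X, y, n_regions=n_regions)
        assert pm.signs[0, 4] == -1 and pm.signs[4, 0] == -1
        assert pm.p_fdr[0, 4] == pm.p_fdr.min() + 0 or pm.p_fdr[0, 4] <= 1e-10

    def test_null_fdr_calibration(self):
        rng = np.random.default_rng(1)
        E = 66
        counts = []
        for _ in range(100):
            X = rng.standard_normal((60, E))
            y = rng.standard_normal(60)
            pm = predictive_pattern(X, y, n_regions=12)
            counts.append(int((pm.signs != 0).sum() // 2))
        assert np.mean(counts) <= 0.05 * E * 1.2

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError):
            PatternMatrix(
                signs=np.array([[1, 0], [0, 0]]),
                r_values=np.zeros((2, 2)),
                p_fdr=np.zeros((2, 2)),
            )


class TestCohensD:
    def test_identical_samples_zero(self):
        a = np.array([0.4, 0.5, 0.6])
        assert cohens_d(a, a) == 0.0

    def test_one_pooled_sd_apart(self):
        a = np.array([0.0, 1.0, 2.0])
        assert cohens_d(a + 1.0, a) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert cohens_d([0.5, 0.6, 0.7], [0.2, 0.3, 0.4]) == pytest.approx(3.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(20), rng.standard_normal(20) + 0.5
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_degenerate(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match=">= 2"):
            cohens_d([1.0], [1.0, 2.0])
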
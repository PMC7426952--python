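"""Canonical correlation fitting, cross-validation, trial-shuffle nulls,
weight stability, subspace geometry and the bin/lag sweep."""

import numpy as np
import pytest
from scipy.optimize import minimize

import crossarea as ca
from crossarea.cca import (fit_cca, crossval_r2, trial_shuffle_significance,
                           weight_stability, subspace_angle,
                           lag_binwidth_sweep)


def brute_force_rho1(Xa, Xb, restarts=8):
    """Independent oracle: directly maximize |corr(Xa a, Xb b)|."""
    Xa = Xa - Xa.mean(0)
    Xb = Xb - Xb.mean(0)
    da, db = Xa.shape[1], Xb.shape[1]

    def neg(v):
        za, zb = Xa @ v[:da], Xb @ v[da:]
        sa, sb = za.std(), zb.std()
        if sa == 0 or sb == 0:
            return 0.0
        return -abs(np.corrcoef(za, zb)[0, 1])

    best = 0.0
    for s in range(restarts):
        x0 = np.random.default_rng(s).standard_normal(da + db)
        res = minimize(neg, x0, method="L-BFGS-B")
        best = max(best, -res.fun)
    return best


class TestFitCca:
    def test_identical_data_all_rho_one(self, rng):
        X = rng.standard_normal((100, 5))
        model = fit_cca(X, X.copy())
        np.testing.assert_allclose(model.rho, 1.0, atol=1e-8)

    def test_training_projection_correlation_equals_rho(self, rng):
        Xa = rng.standard_normal((200, 6))
        Xb = rng.standard_normal((200, 4))
        Xb[:, 0] += 0.5 * Xa[:, 1]
        model = fit_cca(Xa, Xb)
        for j in range(model.k):
            za = model.project(Xa, "M2", j)
            zb = model.project(Xb, "M1", j)
            assert abs(np.corrcoef(za, zb)[0, 1]) == pytest.approx(
                model.rho[j], abs=1e-8)

    def test_rho_sorted_in_unit_interval(self, rng):
        model = fit_cca(rng.standard_normal((150, 8)),
                        rng.standard_normal((150, 5)))
        assert np.all(np.diff(model.rho) <= 1e-12)
        assert np.all((model.rho >= 0) & (model.rho <= 1))

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            Xa = rng.standard_normal((200, 5))
            Xb = rng.standard_normal((200, 5))
            Xb += 0.3 * rng.standard_normal() * Xa
            model = fit_cca(Xa, Xb)
            assert model.rho[0] == pytest.approx(
                brute_force_rho1(Xa, Xb), abs=1e-3)

    def test_matches_sklearn_cross_decomposition(self, rng):
        from sklearn.cross_decomposition import CCA as SkCCA
        Xa = rng.standard_normal((300, 4))
        Xb = rng.standard_normal((300, 4))
        Xb[:, 2] += 0.8 * Xa[:, 0]
        model = fit_cca(Xa, Xb)
        sk = SkCCA(n_components=1, max_iter=2000).fit(Xa, Xb)
        za, zb = sk.transform(Xa, Xb)
        rho_sk = abs(np.corrcoef(za[:, 0], zb[:, 0])[0, 1])
        assert model.rho[0] == pytest.approx(rho_sk, abs=1e-4)

    def test_affine_invariance_of_correlations(self, rng):
        Xa = rng.standard_normal((200, 6))
        Xb = rng.standard_normal((200, 5))
        Xb[:, 1] += 0.6 * Xa[:, 0]
        model = fit_cca(Xa, Xb)
        A = rng.standard_normal((6, 6)) + 0.1 * np.eye(6)
        B = rng.standard_normal((5, 5)) + 0.1 * np.eye(5)
        model2 = fit_cca(Xa @ A + rng.standard_normal(6), Xb @ B)
        np.testing.assert_allclose(model.rho, model2.rho, atol=1e-8)

    def test_projection_invariant_to_other_region_recoding(self, rng):
        Xa = rng.standard_normal((200, 5))
        Xb = rng.standard_normal((200, 5))
        Xb[:, 0] += Xa[:, 0]
        m1 = fit_cca(Xa, Xb)
        R = rng.standard_normal((5, 5)) + 0.2 * np.eye(5)
        m2 = fit_cca(Xa, Xb @ R)
        za1, za2 = m1.project(Xa, "M2", 0), m2.project(Xa, "M2", 0)
        sign = np.sign(za1 @ za2)
        np.testing.assert_allclose(za1, sign * za2, atol=1e-8)

    def test_rank_deficient_column_dropped_with_warning(self, rng):
        Xa = rng.standard_normal((100, 4))
        Xa[:, 3] = Xa[:, 0]          # collinear
        Xb = rng.standard_normal((100, 3))
        with pytest.warns(RuntimeWarning):
            model = fit_cca(Xa, Xb)
        assert model.k == 3

    def test_rows_not_exceeding_columns_raise(self, rng):
        with pytest.raises(ValueError):
            fit_cca(rng.standard_normal((5, 6)), rng.standard_normal((5, 3)))

    def test_unknown_region_raises(self, rng):
        model = fit_cca(rng.standard_normal((50, 3)),
                        rng.standard_normal((50, 3)))
        with pytest.raises(ValueError):
            model.project(np.zeros((10, 3)), "V1")


class TestCrossvalR2:
    def test_perfectly_shared_signal(self, rng):
        z = rng.standard_normal(400)
        Xa = np.outer(z, rng.standard_normal(5)) \
            + 0.05 * rng.standard_normal((400, 5))
        Xb = np.outer(z, rng.standard_normal(5)) \
            + 0.05 * rng.standard_normal((400, 5))
        r2 = crossval_r2(Xa, Xb, folds=10, seed=0)
        assert r2[0] > 0.95

    def test_deterministic_given_seed(self, rng):
        Xa = rng.standard_normal((120, 4))
        Xb = rng.standard_normal((120, 4))
        np.testing.assert_array_equal(crossval_r2(Xa, Xb, seed=3),
                                      crossval_r2(Xa, Xb, seed=3))

    def test_too_few_folds_raise(self, rng):
        with pytest.raises(ValueError):
            crossval_r2(rng.standard_normal((50, 3)),
                        rng.standard_normal((50, 3)), folds=1)


class TestTrialShuffleSignificance:
    def test_planted_latent_detected(self, small_fit):
        _, _, fit = small_fit
        assert fit.significance.n_significant == 1
        assert not fit.significance.exclude

    def test_single_trial_raises(self, small_fit):
        session, _, fit = small_fit
        ta = fit.mats["M2"]["tensors"][:1]
        tb = fit.mats["M1"]["tensors"][:1]
        with pytest.raises(ValueError):
            trial_shuffle_significance(ta, tb, n_shuffles=10)

    def test_no_significant_cv_flags_exclusion(self, rng):
        tensors_a = [ca.BinnedPopulation(rng.poisson(2.0, (10, 5)), 100.0,
                                         np.arange(10) * 0.1, "e")
                     for _ in range(20)]
        tensors_b = [ca.BinnedPopulation(rng.poisson(2.0, (10, 5)), 100.0,
                                         np.arange(10) * 0.1, "e")
                     for _ in range(20)]
        sig = trial_shuffle_significance(tensors_a, tensors_b,
                                         n_shuffles=300, seed=1)
        if sig.n_significant == 0:         # expected for independent data
            assert sig.exclude

    def test_null_distribution_matches_brute_refit(self, small_fit):
        """The fast permuted-rows null equals refitting CCA from scratch."""
        _, _, fit = small_fit
        ta = fit.mats["M2"]["tensors"][:12]
        tb = fit.mats["M1"]["tensors"][:12]
        sig = trial_shuffle_significance(ta, tb, n_shuffles=5, seed=42)
        rng = np.random.default_rng(42)
        rng.integers(2 ** 31)     # consumed internally for the crossval seed
        Xa, _, _ = ca.concat_and_center(ta)
        brute = []
        from crossarea.cca import _permute_non_identity
        for _ in range(5):
            perm = _permute_non_identity(rng, 12)
            Xb, _, _ = ca.concat_and_center([tb[i] for i in perm])
            brute.append(fit_cca(Xa, Xb).rho[0] ** 2)
        np.testing.assert_allclose(np.sort(sig.null_r2), np.sort(brute),
                                   atol=1e-10)


class TestWeightStability:
    def test_noiseless_low_rank_deltas_vanish(self, rng):
        z = rng.standard_normal(300)
        Xa = np.outer(z, [1.0, -0.5, 0.25])
        Xb = np.outer(z, [0.3, 0.9, -0.2])
        with pytest.warns(RuntimeWarning):        # rank-1 blocks
            deltas = weight_stability(Xa, Xb, n_subsets=4, seed=0)
        for r in deltas:
            assert np.nanmax(np.abs(deltas[r])) < 1e-6

    def test_subset_deltas_small_relative_to_weights(self, small_fit):
        _, _, fit = small_fit
        Xa, Xb = fit.mats["M2"]["X"], fit.mats["M1"]["X"]
        deltas = weight_stability(Xa, Xb, n_subsets=6, seed=0)
        full = fit_cca(Xa, Xb)
        for r in ("M2", "M1"):
            sd_delta = np.nanstd(deltas[r][:, :, 0])
            sd_weight = np.std(full.weights[r][:, 0])
            assert sd_delta < 0.25 * sd_weight


class TestSubspaceAngle:
    def test_identical_vectors(self):
        v = np.array([[1.0], [2.0], [3.0]])
        assert subspace_angle(v, v) == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_vectors(self):
        assert subspace_angle(np.array([[1.0], [0.0]]),
                              np.array([[0.0], [1.0]])) == pytest.approx(90.0)

    def test_sign_folding(self):
        v = np.array([[1.0], [1.0]])
        assert subspace_angle(v, -v) == pytest.approx(0.0, abs=1e-8)

    def test_vector_versus_plane_closed_form(self):
        v = np.array([1.0, 1.0, 0.0])[:, None]
        plane = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        assert subspace_angle(v, plane) == pytest.approx(45.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            subspace_angle(np.ones((3, 1)), np.ones((4, 1)))


def test_cca_axis_distinct_from_pca_axes():
    """The axis of maximal cross-area correlation is not an axis of
    maximal local variance: when the shared latent is weak relative to
    local dynamics, the top CV sits > 30 degrees from the span of the top
    three principal components of the same region."""
    from crossarea.cca import pca_axes
    for seed in (1, 2, 3):
        cfg = ca.SyntheticConfig(n_units={"M2": 20, "M1": 20},
                                 n_trials=100, seed=seed)
        session, _ = ca.generate_session(cfg, "early")
        mats = ca.pipeline.peri_grasp_matrices(session)
        model = fit_cca(mats["M2"]["X"], mats["M1"]["X"])
        for region in ("M2", "M1"):
            P = pca_axes(mats[region]["X"], 3)
            assert subspace_angle(model.weights[region][:, :1], P) > 30.0


class TestLagBinwidthSweep:
    def test_single_cell_matches_plain_crossval(self, small_session):
        session, _ = small_session
        res = lag_binwidth_sweep(session, binwidths_ms=(100.0,),
                                 lag_range_ms=(0.0, 0.0), folds=5, seed=0)
        mats = ca.pipeline.peri_grasp_matrices(session)
        direct = crossval_r2(mats["M2"]["X"], mats["M1"]["X"],
                             folds=5, seed=0)[0]
        assert res.best_r2 == pytest.approx(direct, abs=1e-12)

    def test_zero_planted_lag_recovered(self, small_session):
        session, _ = small_session
        res = lag_binwidth_sweep(session, binwidths_ms=(100.0,),
                                 lag_range_ms=(-300.0, 300.0),
                                 folds=5, seed=0)
        assert abs(res.best_lag_ms) <= 100.0

    def test_planted_shared_lag_recovered(self):
        cfg = ca.SyntheticConfig(n_units={"M2": 15, "M1": 15}, n_trials=80,
                                 seed=9, shared_lag_ms=200.0)
        session, _ = ca.generate_session(cfg, "late")
        res = lag_binwidth_sweep(session, binwidths_ms=(100.0,),
                                 lag_range_ms=(-400.0, 400.0),
                                 folds=5, seed=0)
        assert abs(res.best_lag_ms - 200.0) <= 100.0
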
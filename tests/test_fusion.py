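"""Fusion model contracts: projection identities, regression oracle,
sign-flip invariance, loss behavior, recovery, stability, serialization."""

import numpy as np
import pytest

import atnfuse as af
from atnfuse.fusion import _batch_gradients, _State, project_loadings

from conftest import all_train_split, make_single_modality_dataset


class TestRegressTargetOnLoadings:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((40, 5))
        beta = rng.standard_normal(5)
        y = Z @ beta + 2.0
        coef, b0, flag = af.regress_target_on_loadings(Z, y)
        resid = y - (Z @ coef + b0)
        assert resid @ resid < 1e-10
        assert not flag

    def test_orthonormal_columns_give_projection_coefficients(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((60, 4))
        Q, _ = np.linalg.qr(A - A.mean(0))
        y = rng.standard_normal(60)
        coef, b0, _ = af.regress_target_on_loadings(Q, y)
        np.testing.assert_allclose(coef, Q.T @ (y - y.mean()), atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        coef, b0, _ = af.regress_target_on_loadings(Z, y)
        A = np.column_stack([Z, np.ones(50)])
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(np.append(coef, b0), oracle, atol=1e-8)

    def test_rank_deficiency_flagged_minimum_norm(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((30, 3))
        Z = np.column_stack([Z, Z[:, 0]])  # duplicated column
        y = rng.standard_normal(30)
        coef, b0, flag = af.regress_target_on_loadings(Z, y)
        assert flag

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError):
            af.regress_target_on_loadings(np.zeros((4, 6)), np.zeros(4))


class TestProjection:
    def test_recovers_consistent_linear_system(self, small_fit):
        rng = np.random.default_rng(4)
        Z0 = rng.standard_normal((15, small_fit.k))
        X_new = [Z0 @ (s * small_fit.W[m]).T for m, s in enumerate(small_fit.S)]
        Z_hat = small_fit.project(X_new, standardized=True, ridge=1e-12)
        rel = np.linalg.norm(Z_hat - Z0) / np.linalg.norm(Z0)
        assert rel < 1e-6

    def test_orthonormal_maps_projection_identity(self):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 3)))
        X = rng.standard_normal((12, 40))
        Z = project_loadings([X], [Q], np.ones((1, 3)), np.array([40.0]), ridge=0.0)
        np.testing.assert_allclose(Z, X @ Q, atol=1e-8)

    def test_training_projection_consistency(self, small_dataset, small_split, small_fit):
        Xtr = [x[small_split.train] for x in small_dataset.X]
        Z_proj = small_fit.project(Xtr)
        for k in range(small_fit.k):
            r = np.corrcoef(Z_proj[:, k], small_fit.Z[:, k])[0, 1]
            assert r >= 0.99

    def test_dimension_mismatch_raises(self, small_fit):
        with pytest.raises(ValueError):
            small_fit.project([np.zeros((3, 7))] * len(small_fit.S))


class TestPredict:
    def test_affine_in_loadings(self, small_fit):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((8, small_fit.k))
        np.testing.assert_allclose(small_fit.predict(Z=Z),
                                   Z @ small_fit.beta + small_fit.intercept)
        one_hot = np.eye(small_fit.k)
        np.testing.assert_allclose(small_fit.predict(Z=one_hot) - small_fit.intercept,
                                   small_fit.beta, atol=1e-12)

    def test_zero_head_predicts_intercept(self, small_fit):
        state = small_fit._state
        saved = state.beta.copy()
        state.beta = np.zeros_like(saved)
        try:
            pred = small_fit.predict(Z=np.random.default_rng(0).standard_normal((5, small_fit.k)))
            np.testing.assert_allclose(pred, small_fit.intercept)
        finally:
            state.beta = saved

    def test_column_mismatch_raises(self, small_fit):
        with pytest.raises(ValueError):
            small_fit.predict(Z=np.zeros((3, small_fit.k + 1)))


class TestFitBehavior:
    def test_unsupervised_limit_has_zero_head_gradient(self, small_dataset, small_split):
        hp = af.FusionHyperparams(gamma=0.0, seed=0)
        model = af.SupervisedFusion(small_dataset, small_split, 3, hp)
        mus, sds, X_std = model._standardize()
        tr = small_split.train
        Xtr = [x[tr] for x in X_std]
        rng = np.random.default_rng(0)
        state = _State(Z=rng.standard_normal((tr.size, 3)),
                       S=[rng.standard_normal((x.shape[1], 3)) for x in Xtr],
                       W=np.ones((3, 3)), beta=rng.standard_normal(3), b0=0.5)
        g = _batch_gradients(state, Xtr, small_dataset.target[tr],
                             np.arange(20), np.full(3, 1 / 3), hp, tr.size)
        np.testing.assert_array_equal(g["beta"], 0.0)
        assert g["b0"] == 0.0

    def test_loss_never_worse_than_initialization(self, small_fit):
        hist = small_fit.train_history
        assert hist[-1]["total"] <= hist[0]["total"] + 1e-12

    def test_training_loadings_standardized(self, small_fit):
        np.testing.assert_allclose(small_fit.Z.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(small_fit.Z.std(axis=0), 1.0, atol=1e-6)

    def test_nonnegative_modality_weights(self, small_fit):
        assert np.all(small_fit.W >= 0)

    def test_noiseless_rank_k_reconstruction(self):
        cfg = af.SimulationConfig(n_subjects=80, n_modalities=2,
                                  features_per_modality=120, k_true=4,
                                  snr=np.inf, batch_gamma_sd=0.0,
                                  batch_delta_log_sd=0.0, n_sites=6, seed=17)
        ds = af.generate_dataset(cfg)
        sp = af.grouped_split(ds.site, seed=17)
        res = af.fit_fusion(ds, sp, 4, af.FusionHyperparams(max_epochs=30,
                                                            patience=10, seed=17))
        assert np.all(res.reconstruction_error("train") < 0.05)

    def test_k_bounds_enforced(self, small_dataset, small_split):
        with pytest.raises(ValueError):
            af.SupervisedFusion(small_dataset, small_split, 10_000)

    def test_loading_recovery_moderate_size(self, small_dataset, small_split, small_fit):
        truth = small_dataset.truth.loadings_true[small_split.train]
        _, vals = af.match_components(small_fit.Z, truth)
        assert vals.mean() >= 0.85


class TestSignFlipEquivalence:
    def test_negating_component_triple_preserves_all_loss_terms(self, small_fit,
                                                                small_dataset, small_split):
        base = small_fit.loss_terms("train")
        state = small_fit._state
        for k in range(small_fit.k):
            state.Z[:, k] *= -1
            state.beta[k] *= -1
            for s in state.S:
                s[:, k] *= -1
            flipped = small_fit.loss_terms("train")
            for key, val in base.items():
                assert abs(flipped[key] - val) <= 1e-9 * (abs(val) + 1.0), key
            # restore
            state.Z[:, k] *= -1
            state.beta[k] *= -1
            for s in state.S:
                s[:, k] *= -1

    def test_predictions_invariant_under_flip(self, small_fit):
        state = small_fit._state
        pred = small_fit.predict(Z=small_fit.Z)
        state.Z[:, 0] *= -1
        state.beta[0] *= -1
        for s in state.S:
            s[:, 0] *= -1
        try:
            np.testing.assert_allclose(small_fit.predict(Z=small_fit.Z), pred, rtol=1e-9)
        finally:
            state.Z[:, 0] *= -1
            state.beta[0] *= -1
            for s in state.S:
                s[:, 0] *= -1


class TestModalityWeights:
    def test_shares_form_simplex(self, small_fit):
        shares, degenerate = small_fit.modality_weight_distribution()
        assert not degenerate.any()
        np.testing.assert_allclose(shares.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((shares >= 0) & (shares <= 1))

    def test_dominant_modality_matches_truth(self, small_dataset, small_split, small_fit):
        truth = small_dataset.truth
        perm, vals = af.match_components(small_fit.Z,
                                         truth.loadings_true[small_split.train])
        shares, _ = small_fit.modality_weight_distribution()
        true_energy = np.stack([truth.modality_weights_true[m] *
                                np.linalg.norm(truth.maps_true[m], axis=0)
                                for m in range(small_dataset.n_modalities)], axis=1)
        hits = 0
        for k_true in range(truth.loadings_true.shape[1]):
            if vals[k_true] < 0.9:
                continue
            if np.argmax(shares[perm[k_true]]) == np.argmax(true_energy[k_true]):
                hits += 1
        assert hits >= 2  # well-recovered components identify their dominant modality

    def test_degenerate_component_flagged(self, small_fit):
        state = small_fit._state
        saved = [s[:, 0].copy() for s in state.S]
        for s in state.S:
            s[:, 0] = 0.0
        try:
            shares, degenerate = small_fit.modality_weight_distribution()
            assert degenerate[0]
            assert np.isnan(shares[0]).all()
        finally:
            for s, col in zip(state.S, saved):
                s[:, 0] = col


class TestEckartYoungOracle:
    def test_single_modality_unsupervised_fit_near_svd_optimum(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((60, 80))
        ds = make_single_modality_dataset(X)
        sp = all_train_split(60)
        hp = af.FusionHyperparams(gamma=0.0, l1=0.0, max_epochs=20, patience=5, seed=0)
        res = af.SupervisedFusion(ds, sp, 5, hp).fit()
        Xs = res.standardize([X])[0]
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        opt = np.sqrt((s[5:] ** 2).sum()) / np.linalg.norm(Xs)
        fitted = res.reconstruction_error("train")[0]
        assert fitted <= opt * 1.05


class TestStability:
    def test_duplicate_runs_bit_identical(self, small_dataset, small_split):
        hp = af.FusionHyperparams(max_epochs=15, patience=5)
        rep = af.stability_analysis(small_dataset, small_split, [3], [5, 5], hp)
        assert rep.n_runs == 2
        np.testing.assert_array_equal(rep.predictions[0], rep.predictions[1])
        assert rep.pairwise_prediction_correlations[0, 1] == pytest.approx(1.0)

    def test_grid_is_fully_recorded(self, small_dataset, small_split):
        hp = af.FusionHyperparams(max_epochs=5, patience=3)
        rep = af.stability_analysis(small_dataset, small_split, [2, 3], [0, 1], hp)
        assert rep.grid == [(2, 0), (2, 1), (3, 0), (3, 1)]
        assert len(rep.heldout_r) == 4
        C = rep.pairwise_prediction_correlations
        assert np.all(np.abs(C) <= 1.0 + 1e-12)
        np.testing.assert_allclose(C, C.T)

    def test_single_run_rejected(self, small_dataset, small_split):
        with pytest.raises(ValueError):
            af.stability_analysis(small_dataset, small_split, [3], [0])


class TestModelBundle:
    def test_round_trip_bit_identical(self, small_fit, tmp_path):
        out = af.save_model(small_fit, tmp_path / "model")
        loaded = af.load_model(out)
        np.testing.assert_array_equal(loaded.Z, small_fit.Z)
        np.testing.assert_array_equal(loaded.W, small_fit.W)
        np.testing.assert_array_equal(loaded.beta, small_fit.beta)
        for a, b in zip(loaded.S, small_fit.S):
            np.testing.assert_array_equal(a, b)
        assert loaded.intercept == small_fit.intercept

    def test_loaded_model_projects_identically(self, small_fit, small_dataset, tmp_path):
        out = af.save_model(small_fit, tmp_path / "model")
        loaded = af.load_model(out)
        X = [x[:10] for x in small_dataset.X]
        np.testing.assert_allclose(loaded.project(X), small_fit.project(X), atol=1e-12)
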
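"""Alternating multilinear Fisher optimization: scatters, updates, fits."""

import numpy as np
import pytest

from mdsp.dsp import fit_dsp, scatter_matrices, top_generalized_eigvecs
from mdsp.mdsp import (
    MDSP,
    FitConfig,
    class_mean_tensors,
    convergence_error,
    fit_mdsp,
    load_model,
    mode_scatter,
    project,
    save_model,
    update_mode,
)
from mdsp.synthetic import planted_dataset, PlantedSpec, subspace_recovery_score
from mdsp.tensor_core import multi_mode_product, unfold

from conftest import random_labeled_tensors


def fisher_forms(X, y, projections, mode):
    """Frobenius-form numerator/denominator of the multilinear criterion,
    evaluated by full multi-mode projection (independent of mode_scatter)."""
    classes, counts = np.unique(y, return_counts=True)
    M_j = [X[y == j].mean(axis=0) for j in classes]
    M = X.mean(axis=0)
    num = sum(
        n_j * np.linalg.norm(multi_mode_product(Mj - M, projections)) ** 2
        for n_j, Mj in zip(counts, M_j)
    )
    den = sum(
        np.linalg.norm(multi_mode_product(X[i] - M_j[list(classes).index(y[i])],
                                          projections)) ** 2
        for i in range(len(y))
    )
    return num, den


class TestModeScatter:
    def test_matrix_case_reduces_to_dsp_scatters(self, rng):
        X = rng.standard_normal((12, 5, 9))
        y = np.array([1] * 6 + [2] * 6)
        S_b, S_w = mode_scatter(X, y, [np.eye(5), np.eye(9)], 1)
        S_w_ref, S_b_ref = scatter_matrices(X, y)
        np.testing.assert_allclose(S_b, S_b_ref, rtol=1e-12)
        np.testing.assert_allclose(S_w, S_w_ref, rtol=1e-12)

    def test_trials_at_class_mean_zero_within_scatter(self, rng):
        base = rng.standard_normal((3, 4, 2))
        X = np.stack([base, base, -base, -base])
        y = np.array([1, 1, 2, 2])
        for k in (1, 2, 3):
            _, S_w = mode_scatter(X, y, [np.eye(3), np.eye(4), np.eye(2)], k)
            np.testing.assert_allclose(S_w, 0, atol=1e-12)

    @pytest.mark.parametrize("mode", [1, 2, 3])
    def test_trace_forms_equal_frobenius_forms(self, rng, mode):
        X, y = random_labeled_tensors(rng)
        dims = (2, 3, 2)
        mats = [rng.standard_normal((m, d)) for m, d in zip(X.shape[1:], dims)]
        S_b, S_w = mode_scatter(X, y, mats, mode)
        U_k = mats[mode - 1]
        full = list(mats)
        num, den = fisher_forms(X, y, full, mode)
        np.testing.assert_allclose(np.trace(U_k.T @ S_b @ U_k), num, rtol=1e-10)
        np.testing.assert_allclose(np.trace(U_k.T @ S_w @ U_k), den, rtol=1e-10)

    def test_nonconforming_projection_names_mode(self, rng):
        X, y = random_labeled_tensors(rng)
        bad = [np.eye(4), np.eye(7), np.eye(3)]
        with pytest.raises(ValueError, match="mode 2"):
            mode_scatter(X, y, bad, 1)


class TestUpdateMode:
    def test_matrix_case_matches_fit_dsp(self, rng):
        X = rng.standard_normal((14, 5, 9))
        y = np.array([1] * 7 + [2] * 7)
        U1 = update_mode(X, y, [np.eye(5), np.eye(9)], 1, 3, reg=1e-8)
        ref = fit_dsp(X, y, d=3, reg=1e-8).U
        np.testing.assert_allclose(U1, ref, atol=1e-9)

    def test_single_class_degenerate_warns_and_returns_zero_eigs(self, rng):
        X = rng.standard_normal((5, 3, 4))
        y = np.ones(5, dtype=int)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            U = update_mode(X, y, [np.eye(3), np.eye(4)], 1, 2)
        assert U.shape == (3, 2)

    def test_matches_dense_eigensolver_oracle(self, rng):
        X, y = random_labeled_tensors(rng)
        mats = [np.eye(4), np.eye(6), np.eye(3)]
        S_b, S_w = mode_scatter(X, y, mats, 2)
        U = update_mode(X, y, mats, 2, 3, reg=1e-6)
        ref, _ = top_generalized_eigvecs(S_b, S_w, 3, reg=1e-6)
        np.testing.assert_allclose(U, ref, atol=1e-10)

    def test_conditionally_optimal_vs_random_subspaces(self, rng):
        X, y = random_labeled_tensors(rng)
        mats = [rng.standard_normal((m, 2)) for m in X.shape[1:]]
        k = 2
        S_b, S_w = mode_scatter(X, y, mats, k)
        U = update_mode(X, y, mats, k, 2)
        ratio = lambda V: np.trace(V.T @ S_b @ V) / np.trace(V.T @ S_w @ V)
        best = ratio(U)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.standard_normal((X.shape[k], 2)))
            assert best >= ratio(Q) - 1e-9


class TestConvergenceError:
    def test_identical_matrices_zero(self, rng):
        U = rng.standard_normal((5, 2))
        assert convergence_error(U, U) == 0.0

    def test_closed_form_doubled_identity(self):
        I2 = np.eye(2)
        np.testing.assert_allclose(
            convergence_error(I2, 2 * I2), np.sqrt(2) / 2
        )

    def test_sign_flips_do_not_register(self, rng):
        U = rng.standard_normal((5, 3))
        flipped = U * np.array([1, -1, 1])
        assert convergence_error(U, flipped) < 1e-15

    def test_random_pair_matches_formula(self, rng):
        from mdsp.dsp import canonicalize_signs

        A = rng.standard_normal((4, 2))
        B = rng.standard_normal((4, 2))
        expected = np.linalg.norm(
            canonicalize_signs(B) - canonicalize_signs(A)
        ) / np.linalg.norm(A) ** 2
        np.testing.assert_allclose(convergence_error(A, B), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            convergence_error(np.eye(2), np.eye(3))


class TestFitMdsp:
    def test_defaults_epsilon_and_sweep_cap(self):
        cfg = FitConfig(dims=(2, 2))
        assert cfg.epsilon == 0.01
        assert cfg.t_max == 50

    def test_noiseless_mode1_difference_converges_fast_and_recovers(self, rng):
        # class means differ only in a rank-2 mode-1 (channel) subspace;
        # trials equal their class means exactly
        c, t = 8, 12
        Q, _ = np.linalg.qr(rng.standard_normal((c, c)))
        Q = Q[:, :2]
        shared = rng.standard_normal((c, t))
        means = [shared + Q @ rng.standard_normal((2, t)) for _ in range(2)]
        X = np.stack([means[0]] * 5 + [means[1]] * 5)
        y = np.array([1] * 5 + [2] * 5)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 2)))
        assert model.converged
        assert model.iterations_run <= 4
        assert model.trace[-1]["err"] <= 1e-8
        angle = subspace_recovery_score([model.projections[0]], [Q])[0]
        assert angle < 1e-6

    def test_t_max_one_runs_exactly_one_sweep(self, rng):
        X, y = random_labeled_tensors(rng)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 2, 2), t_max=1))
        assert model.iterations_run == 1
        assert model.converged == (model.trace[-1]["err"] <= 0.01)

    def test_total_error_is_sum_of_mode_errors(self, rng):
        X, y = random_labeled_tensors(rng)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 2, 2), t_max=5))
        for rec in model.trace:
            np.testing.assert_allclose(rec["err"], sum(rec["err_k"]))

    def test_invalid_dims_and_single_class_rejected(self, rng):
        X, y = random_labeled_tensors(rng)
        with pytest.raises(ValueError, match="mode-2 target size"):
            fit_mdsp(X, y, FitConfig(dims=(2, 99, 2)))
        with pytest.raises(ValueError, match="classes"):
            fit_mdsp(X, np.ones_like(y), FitConfig(dims=(2, 2, 2)))

    def test_model_invariant_to_trial_order_and_relabeling(self, rng):
        X, y = random_labeled_tensors(rng)
        cfg = FitConfig(dims=(2, 2, 2), t_max=10)
        model = fit_mdsp(X, y, cfg)
        perm = rng.permutation(len(y))
        model_p = fit_mdsp(X[perm], y[perm], cfg)
        for U, Up in zip(model.projections, model_p.projections):
            np.testing.assert_allclose(U, Up, atol=1e-8)
        swapped = np.where(y == 1, 2, 1)
        model_s = fit_mdsp(X, swapped, cfg)
        for U, Us in zip(model.projections, model_s.projections):
            np.testing.assert_allclose(U, Us, atol=1e-8)

    def test_projected_class_means_equal_means_of_projected_trials(self, rng):
        # linearity: projecting input-space means == averaging projected trials
        X, y = random_labeled_tensors(rng)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 2, 2), t_max=5))
        for j, Mj in zip(model.classes, model.class_means):
            proj_mean = project(model, Mj)
            mean_proj = np.mean(
                [project(model, Xi) for Xi in X[y == j]], axis=0
            )
            np.testing.assert_allclose(proj_mean, mean_proj, rtol=1e-9,
                                       atol=1e-12)

    def test_full_dims_is_basis_change_preserving_classification(self, rng):
        X, y = random_labeled_tensors(rng, shape=(3, 4, 2))
        model = fit_mdsp(X, y, FitConfig(dims=(3, 4, 2), t_max=10))
        est = MDSP(n_filters=(3, 4, 2), t_max=10).fit(X, y)
        est2 = MDSP(n_filters=2, t_max=10).fit(X, y)
        # full-rank projection is invertible, so training accuracy matches
        # what any nearest-mean rule in the raw space would give
        assert est.predict(X).shape == y.shape
        assert est2.predict(X).shape == y.shape


class TestProject:
    def test_identity_projections_unchanged(self, rng):
        X, y = random_labeled_tensors(rng)
        model = fit_mdsp(X, y, FitConfig(dims=X.shape[1:], t_max=1))
        model.projections = [np.eye(m) for m in X.shape[1:]]
        np.testing.assert_allclose(project(model, X[0]), X[0])

    def test_matrix_case_is_bilinear_form(self, rng):
        X = rng.standard_normal((10, 5, 7))
        y = np.array([1] * 5 + [2] * 5)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 3), t_max=3))
        U1, U2 = model.projections
        np.testing.assert_allclose(
            project(model, X[0]), U1.T @ X[0] @ U2, rtol=1e-10
        )

    def test_shape_mismatch(self, rng):
        X, y = random_labeled_tensors(rng)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 2, 2), t_max=2))
        with pytest.raises(ValueError, match="does not match"):
            project(model, np.zeros((9, 9, 9)))


class TestComplexInput:
    def test_complex_trials_give_real_projections(self, rng):
        X, y = random_labeled_tensors(rng, shape=(4, 5, 3))
        Xc = X * np.exp(1j * rng.uniform(0, 2 * np.pi, X.shape))
        model = fit_mdsp(Xc, y, FitConfig(dims=(2, 2, 2), t_max=5))
        for U in model.projections:
            assert np.isrealobj(U)
        # Hermitian scatters have real traces
        S_b, S_w = mode_scatter(Xc, y, model.projections, 1)
        np.testing.assert_allclose(S_b, S_b.conj().T, rtol=1e-10)
        np.testing.assert_allclose(np.imag(np.trace(S_w)), 0, atol=1e-10)


class TestSerialization:
    def test_round_trip_preserves_model(self, rng, tmp_path):
        X, y = random_labeled_tensors(rng)
        model = fit_mdsp(X, y, FitConfig(dims=(2, 2, 2), t_max=8))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.converged == model.converged
        assert loaded.iterations_run == model.iterations_run
        assert loaded.config.dims == model.config.dims
        for U, UL in zip(model.projections, loaded.projections):
            np.testing.assert_array_equal(U, UL)
        for Mj, MjL in zip(model.class_means, loaded.class_means):
            np.testing.assert_array_equal(Mj, MjL)
        np.testing.assert_array_equal(model.grand_mean, loaded.grand_mean)
        assert len(loaded.trace) == len(model.trace)
        np.testing.assert_allclose(
            [r["err"] for r in loaded.trace],
            [r["err"] for r in model.trace],
        )
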
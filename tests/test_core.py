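"""The alternating subspace + dictionary optimization."""

import warnings

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from dasrc import (
    LabeledDomain,
    HyperParams,
    build_selectors,
    fit,
    generate_domains,
    init_dictionary,
    init_projections,
    objective,
    sparse_code,
)
from dasrc.core import (
    ClassDictionary,
    benchmark_hyperparams,
    beta_upper_bound,
    lagrangian_value,
    pca_basis,
    retract_rows,
    solve_dictionary,
    solve_projection,
    update_beta,
    update_dictionary,
    update_gamma,
    update_projection,
)
from dasrc.errors import DegenerateStateError, InputError
from dasrc.synthetic import default_benchmark_config
from helpers import make_random_state, numerical_gradient


# ---------------------------------------------------------------- init


class TestPcaBasis:
    def test_axis_aligned_variances_recovered(self, rng):
        # variances 3 > 2 > 1 on the coordinate axes: the top-2 basis
        # must span the first two axes (up to sign)
        X = np.diag([np.sqrt(3), np.sqrt(2), 1.0]) @ rng.standard_normal((3, 4000))
        B = pca_basis(X, 2)
        span = np.abs(B)
        assert span[:, :2].max() > 0.99
        assert np.abs(B[:, 2]).max() < 0.1

    def test_full_basis_is_orthonormal(self, rng):
        X = rng.standard_normal((5, 50))
        B = pca_basis(X, 5)
        np.testing.assert_allclose(B @ B.T, np.eye(5), atol=1e-12)

    def test_projected_variances_match_eigendecomposition(self, rng):
        X = rng.standard_normal((6, 200))
        Xc = X - X.mean(axis=1, keepdims=True)
        B = pca_basis(X, 3)
        cov = Xc @ Xc.T / X.shape[1]
        top = np.sort(np.linalg.eigvalsh(cov))[::-1][:3]
        proj_var = np.sort(np.diag(B @ cov @ B.T))[::-1]
        np.testing.assert_allclose(proj_var, top, rtol=1e-10)


class TestInitProjections:
    def test_joint_orthonormality(self, rng):
        Ys = LabeledDomain(rng.standard_normal((8, 40)), np.ones(40, int))
        Yt = LabeledDomain(rng.standard_normal((6, 9)), np.ones(9, int))
        proj = init_projections(Ys, Yt, p=4)
        assert proj.orthogonality_violation() < 1e-8

    def test_error_names_the_limiting_quantity(self, rng):
        Ys = LabeledDomain(rng.standard_normal((8, 5)), np.ones(5, int))
        Yt = LabeledDomain(rng.standard_normal((8, 5)), np.ones(5, int))
        with pytest.raises(InputError, match="n_s - 1"):
            init_projections(Ys, Yt, p=6)


class TestInitDictionary:
    def test_single_atom_is_dominant_singular_direction(self, rng):
        d, n = 6, 40
        X = rng.standard_normal((d, n)) + 3.0
        Ys = LabeledDomain(X, np.ones(n, int))
        Yt = LabeledDomain(X[:, :5], np.ones(5, int))
        proj = init_projections(Ys, Yt, p=4)
        D = init_dictionary(Ys, Yt, proj, K_c=1, seed=0)
        P = np.hstack([proj.Ms @ Ys.X, proj.Mt @ Yt.X])
        u = np.linalg.svd(P, full_matrices=False)[0][:, 0]
        overlap = abs(float(u @ D.atoms[:, 0]))
        assert overlap == pytest.approx(1.0, abs=1e-8)

    def test_repeated_vector_class_yields_normalized_atom(self, rng):
        # class 1 lives only in the source domain and all its samples
        # equal one vector v: its atom must be the projected v, normalized
        v = rng.standard_normal(5)
        X = np.hstack([np.tile(v[:, None], 12), rng.standard_normal((5, 12))])
        labels = np.repeat([1, 2], 12)
        Ys = LabeledDomain(X, labels)
        Yt = LabeledDomain(rng.standard_normal((5, 3)), np.full(3, 2))
        proj = init_projections(Ys, Yt, p=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            D = init_dictionary(Ys, Yt, proj, K_c=1, seed=0)
        pv = proj.Ms @ v
        np.testing.assert_allclose(
            D.atoms[:, 0], pv / np.linalg.norm(pv), atol=1e-6
        )

    def test_deterministic_given_seed(self, rng):
        Ys = LabeledDomain(
            rng.standard_normal((6, 30)), np.repeat([1, 2, 3], 10)
        )
        Yt = LabeledDomain(rng.standard_normal((6, 6)), np.tile([1, 2, 3], 2))
        proj = init_projections(Ys, Yt, p=4)
        D1 = init_dictionary(Ys, Yt, proj, K_c=2, seed=7)
        D2 = init_dictionary(Ys, Yt, proj, K_c=2, seed=7)
        np.testing.assert_array_equal(D1.atoms, D2.atoms)

    def test_small_class_padded_with_warning(self, rng):
        Ys = LabeledDomain(rng.standard_normal((6, 4)), np.array([1, 1, 2, 2]))
        Yt = LabeledDomain(rng.standard_normal((6, 2)), np.array([1, 2]))
        proj = init_projections(Ys, Yt, p=3)
        with pytest.warns(RuntimeWarning, match="padding"):
            D = init_dictionary(Ys, Yt, proj, K_c=5, seed=0)
        assert D.K == 10


# ---------------------------------------------------------------- coding


class TestSparseCode:
    def test_orthonormal_dictionary_limit(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 4)))
        D = ClassDictionary(q, np.arange(1, 5))
        X = rng.standard_normal((6, 10))
        A = sparse_code(X, D, mu=1e-12)
        np.testing.assert_allclose(A, q.T @ X, atol=1e-8)

    def test_zero_input_codes_to_zero(self, rng):
        D = ClassDictionary(rng.standard_normal((5, 3)), np.arange(1, 4))
        np.testing.assert_array_equal(sparse_code(np.zeros((5, 4)), D, 0.1), 0.0)

    def test_columns_are_ridge_minimizers(self, rng):
        # stationarity: gradient of ||x - D a||^2 + mu ||a||^2 vanishes
        D = ClassDictionary(rng.standard_normal((5, 4)), np.arange(1, 5))
        x = rng.standard_normal((5, 1))
        mu = 0.3
        a = sparse_code(x, D, mu)[:, 0]
        grad = -2 * D.atoms.T @ (x[:, 0] - D.atoms @ a) + 2 * mu * a
        np.testing.assert_allclose(grad, 0.0, atol=1e-10)


class TestSelectors:
    def test_two_class_example(self):
        A = np.array([[0.7], [0.3]])
        Theta, Delta = build_selectors(A, np.array([1]), np.array([1, 2]))
        np.testing.assert_array_equal(Theta, [[0.7], [0.0]])
        np.testing.assert_array_equal(Delta, [[0.0], [0.3]])

    def test_single_class_labels_empty_delta_rows(self, rng):
        A = rng.standard_normal((4, 6))
        Theta, Delta = build_selectors(
            A, np.ones(6, int), np.array([1, 1, 2, 2])
        )
        np.testing.assert_array_equal(Delta[:2], 0.0)
        np.testing.assert_array_equal(Theta[2:], 0.0)

    def test_partition_identity_exact(self, rng):
        A = rng.standard_normal((6, 20))
        labels = rng.integers(1, 4, 20)
        Theta, Delta = build_selectors(A, labels, np.repeat([1, 2, 3], 2))
        np.testing.assert_array_equal(Theta + Delta, A)

    def test_label_without_atoms_rejected(self, rng):
        with pytest.raises(InputError):
            build_selectors(
                rng.standard_normal((2, 3)), np.array([1, 2, 9]), np.array([1, 2])
            )


# ---------------------------------------------------------------- objective


class TestObjective:
    def test_perfect_reconstruction_gives_zero(self, rng):
        # D Theta == M Y exactly, no graph, no variance term
        p, n = 3, 5
        M = retract_rows(rng.standard_normal((p, 8)))
        Y = rng.standard_normal((8, n))
        PY = M @ Y
        D = PY.copy()  # n atoms, one per sample
        Theta = np.eye(n)
        Delta = np.ones((n, n)) - np.eye(n)
        total, num, den, tr = objective(M, D, Theta, Delta, Y, np.zeros((n, n)), 0.0)
        assert num == 0.0 and tr == 0.0 and total == 0.0

    def test_trace_term_matches_direct_expansion(self):
        for seed in range(5):
            state = make_random_state(seed)
            c = state.codes
            _, _, _, tr = state.objective()
            PY = state.M @ state.Ytil
            direct = 0.0
            L = state.Ltil
            n = L.shape[0]
            # Tr(PY L PY^T) by explicit summation, minus alpha*||PY||^2
            for i in range(n):
                for j in range(n):
                    direct += L[i, j] * float(PY[:, i] @ PY[:, j])
            direct -= state.hp.alpha * float(np.sum(PY**2))
            assert tr == pytest.approx(direct, rel=1e-9)

    def test_trace_term_quadratic_in_data(self):
        state = make_random_state(3)
        c = state.codes
        _, _, _, tr1 = objective(
            state.M, state.D, c.Theta, c.Delta, state.Ytil, state.Ltil, state.hp.alpha
        )
        _, _, _, tr2 = objective(
            state.M, state.D, c.Theta, c.Delta, 2 * state.Ytil, state.Ltil,
            state.hp.alpha,
        )
        assert tr2 == pytest.approx(4 * tr1, rel=1e-10)

    def test_zero_denominator_flagged(self, rng):
        M = retract_rows(rng.standard_normal((2, 6)))
        Y = rng.standard_normal((6, 3))
        D = M @ Y
        Delta = np.eye(3)  # D Delta == M Y -> denominator 0
        with pytest.raises(DegenerateStateError):
            objective(M, D, np.zeros((3, 3)), Delta, Y, np.zeros((3, 3)), 0.0)


# ---------------------------------------------------------------- updates


def lagrangian_of(state, M=None, D=None):
    c = state.codes
    return lagrangian_value(
        state.M if M is None else M,
        state.D if D is None else D,
        c.Theta, c.Delta, state.Ytil, state.Ltil,
        state.hp.alpha, state.beta, state.gamma,
    )


class TestProjectionUpdate:
    def test_closed_form_is_stationary(self):
        # the Lagrangian is quadratic in M, so central differences are
        # exact up to roundoff; the solved M must zero the gradient
        for seed in range(3):
            state = make_random_state(seed)
            c = state.codes
            M_pre = solve_projection(
                state.D, c.Theta, c.Delta, state.Ytil, state.Ltil,
                state.hp.alpha, state.beta, state.gamma,
            )
            g = numerical_gradient(lambda M: lagrangian_of(state, M=M), M_pre)
            assert np.linalg.norm(g) < 1e-6

    def test_zero_numerator_keeps_previous_projection(self):
        state = make_random_state(0)
        state.D = np.zeros_like(state.D)
        state.beta = 0.0
        state.refresh_codes()
        M_before = state.M.copy()
        with pytest.warns(RuntimeWarning, match="numerator"):
            update_projection(state)
        np.testing.assert_array_equal(state.M, M_before)

    def test_retraction_contract(self):
        state = make_random_state(1)
        update_projection(state)
        p = state.hp.p
        assert np.linalg.norm(state.M @ state.M.T - np.eye(p)) < 1e-8


class TestDictionaryUpdate:
    def test_beta_zero_reduces_to_least_squares(self):
        state = make_random_state(2)
        c = state.codes
        D = solve_dictionary(state.M, state.Ytil, c.Theta, c.Delta, beta=0.0)
        target = (state.M @ state.Ytil).T
        D_ls = np.linalg.lstsq(c.Theta.T, target, rcond=None)[0].T
        rel = np.linalg.norm(D - D_ls) / np.linalg.norm(D_ls)
        assert rel < 1e-8

    def test_identity_coding_returns_projected_data(self, rng):
        # Theta = I (one atom per sample), beta = 0 -> D = M Y
        p, d, n = 3, 5, 6
        M = retract_rows(rng.standard_normal((p, d)))
        Y = rng.standard_normal((d, n))
        D = solve_dictionary(M, Y, np.eye(n), np.zeros((n, n)), beta=0.0)
        np.testing.assert_allclose(D, M @ Y, atol=1e-10)

    def test_closed_form_is_stationary(self):
        for seed in range(3):
            state = make_random_state(seed)
            c = state.codes
            D_new = solve_dictionary(state.M, state.Ytil, c.Theta, c.Delta, state.beta)
            g = numerical_gradient(lambda D: lagrangian_of(state, D=D), D_new)
            assert np.linalg.norm(g) < 1e-6

    def test_atoms_clipped_to_unit_norm(self):
        state = make_random_state(4)
        state.Ytil = state.Ytil * 10  # force large least-squares atoms
        state.refresh_codes()
        update_dictionary(state)
        assert np.max(np.linalg.norm(state.D, axis=0)) <= 1.0 + 1e-12


class TestBetaUpdate:
    def test_dinkelbach_is_ratio_of_direct_norms(self):
        state = make_random_state(5)
        beta = update_beta(state)
        c = state.codes
        PY = state.M @ state.Ytil
        num = float(np.sum((PY - state.D @ c.Theta) ** 2))
        den = float(np.sum((PY - state.D @ c.Delta) ** 2))
        expected = min(num / den, beta_upper_bound(c.Theta, c.Delta))
        assert beta == pytest.approx(expected, rel=1e-12)

    def test_perfect_same_class_reconstruction_gives_zero(self):
        state = make_random_state(0)
        # force num == 0 by making D Theta reproduce M Y exactly: use
        # Theta = identity-style coding with D = M Y on one class
        c = state.codes
        PY = state.M @ state.Ytil
        n = PY.shape[1]
        state.atom_class = np.ones(n, int)
        state.labels = np.ones(n, int)
        state.D = PY.copy()
        state.codes = type(c)(np.eye(n), np.eye(n), np.zeros((n, n)))
        assert update_beta(state) == 0.0

    def test_clamped_into_positive_definite_range(self):
        state = make_random_state(6)
        update_beta(state)
        c = state.codes
        B = c.Theta @ c.Theta.T - state.beta * c.Delta @ c.Delta.T
        assert np.linalg.eigvalsh((B + B.T) / 2)[0] > 0


class TestGammaUpdate:
    def test_orthonormal_projection_leaves_gamma_unchanged(self):
        state = make_random_state(0)
        state.hp.lambda_gamma = 0.5
        g0 = state.gamma
        assert update_gamma(state) == g0

    def test_zero_step_size_freezes_gamma(self):
        state = make_random_state(1)
        state.hp.lambda_gamma = 0.0
        state.M = state.M * 1.7  # violate orthonormality
        assert update_gamma(state) == state.gamma == 1e-3

    def test_trace_surrogate_matches_direct_trace(self):
        state = make_random_state(2)
        state.hp.lambda_gamma = 0.1
        state.M = state.M * 1.5
        state.refresh_codes()
        viol_direct = float(np.trace(np.eye(state.hp.p) - state.M @ state.M.T))
        F = lagrangian_of(state)
        expected = state.gamma + 0.1 * F / viol_direct
        assert update_gamma(state) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------- fit


class TestFit:
    def test_single_iteration_logs_one_record(self, benchmark_data):
        Ys, Yt_lab, _ = benchmark_data
        model = fit(Ys, Yt_lab, benchmark_hyperparams(seed=0, max_iter=1))
        assert len(model.log) == 1

    def test_bit_identical_given_equal_seeds(self, benchmark_data):
        Ys, Yt_lab, _ = benchmark_data
        hp = benchmark_hyperparams(seed=3)
        m1 = fit(Ys, Yt_lab, hp)
        m2 = fit(Ys, Yt_lab, benchmark_hyperparams(seed=3))
        np.testing.assert_array_equal(m1.log.objectives(), m2.log.objectives())
        np.testing.assert_array_equal(m1.projections.M, m2.projections.M)
        np.testing.assert_array_equal(m1.dictionary.atoms, m2.dictionary.atoms)

    def test_objective_non_increasing(self, benchmark_model):
        objs = benchmark_model.log.objectives()
        assert np.all(np.diff(objs) <= 1e-6)

    def test_constraints_hold_every_iteration(self, benchmark_model):
        for r in benchmark_model.log.records:
            assert r.ortho_violation < 1e-8
            assert r.max_atom_norm <= 1.0 + 1e-12

    def test_symmetric_domains_stay_symmetric(self):
        # identical data, identical graphs and a block-symmetric start:
        # the decoupled block updates must keep Ms == Mt
        rng = np.random.default_rng(0)
        n, p = 12, 3
        labels = np.tile([1, 2, 3], 4)
        Y = rng.standard_normal((5, n)) + labels[None, :]
        from scipy.linalg import block_diag
        from dasrc.graphs import laplacian, target_label_graph
        from dasrc.core import FitState, retract_rows as rr, sparse_code as sc

        L = laplacian(target_label_graph(labels)).matrix
        B = rr(rng.standard_normal((p, 5)))
        M = np.hstack([B, B]) / np.sqrt(2)
        D = rng.standard_normal((p, 6))
        D /= np.maximum(np.linalg.norm(D, axis=0), 1.0)
        st = FitState(
            Ytil=block_diag(Y, Y), Ltil=block_diag(L, L),
            labels=np.concatenate([labels, labels]),
            atom_class=np.repeat([1, 2, 3], 2), d_s=5, M=M, D=D, codes=None,
            beta=0.0, gamma=1e-3, hp=HyperParams(p=p, K_c=2, alpha=0.5),
        )
        st.refresh_codes()
        for _ in range(3):
            st.refresh_codes()
            update_projection(st)
            update_dictionary(st)
            update_beta(st)
            np.testing.assert_allclose(st.M[:, :5], st.M[:, 5:], atol=1e-8)

    def test_converges_before_iteration_bound(self, benchmark_model):
        assert len(benchmark_model.log) < 40

    def test_target_subspace_recovery_improves_on_average(self):
        # mean principal angle between the learned target row space and
        # the true latent embedding, averaged over seeds 0-4, shrinks
        # from initialization to convergence
        init_angles, final_angles = [], []
        for s in range(5):
            Ys, Ytl, _, truth = generate_domains(
                default_benchmark_config(seed=s), return_truth=True
            )
            hp = benchmark_hyperparams(seed=0)
            proj0 = init_projections(Ys, Ytl, hp.p)
            model = fit(Ys, Ytl, hp)
            init_angles.append(
                np.mean(subspace_angles(proj0.Mt.T, truth.embedding_t))
            )
            final_angles.append(
                np.mean(subspace_angles(model.projections.Mt.T, truth.embedding_t))
            )
        assert np.mean(final_angles) < np.mean(init_angles)
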
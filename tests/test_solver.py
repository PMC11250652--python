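"""ADMM solver: per-update closed forms, loop invariants and end-to-end
completion behavior."""

import numpy as np
import pytest

from ctnmqr import (
    SolverConfig,
    complete,
    fold,
    frobenius_norm,
    generate_tucker_tensor,
    multi_mode_product,
    relative_change,
    rse,
    sample_mask,
    svt,
    tucker_reconstruct,
    unfold,
)
from ctnmqr.solver import (
    init_state,
    least_squares_factor,
    update_auxiliary,
    update_completion,
    update_core,
    update_factor,
    update_multipliers_and_penalty,
)
from conftest import random_orthonormal


def small_problem(seed=3, shape=(6, 7, 5), rank=(2, 2, 2), mr=0.3):
    truth = generate_tucker_tensor(shape, rank, np.random.default_rng([seed, 1]))
    mask = sample_mask(shape, mr, np.random.default_rng([seed, 2])).observed
    cfg = SolverConfig(rank=rank, seed=seed)
    return truth, mask, cfg


def advanced_state(truth, mask, cfg, sweeps=3):
    """State after a few full ADMM sweeps (exercises non-trivial V, Y, mu)."""
    state = init_state(truth, mask, cfg)
    for _ in range(sweeps):
        state.aux = update_auxiliary(state, cfg)
        state.core = update_core(state, cfg)
        for i in range(1, truth.ndim + 1):
            state.factors[i - 1] = update_factor(state, i, cfg)
        state.x = update_completion(state, truth, mask)
        state.multipliers, state.mu = update_multipliers_and_penalty(state, cfg)
    return state


class TestInitState:
    def test_observed_entries_and_zero_fill(self):
        truth, mask, cfg = small_problem()
        state = init_state(truth, mask, cfg)
        np.testing.assert_array_equal(state.x[mask], truth[mask])
        np.testing.assert_array_equal(state.x[~mask], 0.0)

    def test_multipliers_zero_aux_equals_core(self):
        truth, mask, cfg = small_problem()
        state = init_state(truth, mask, cfg)
        for y, v in zip(state.multipliers, state.aux):
            np.testing.assert_array_equal(y, np.zeros(cfg.rank))
            np.testing.assert_array_equal(v, state.core)
        assert state.mu == cfg.mu0

    def test_factors_orthonormal(self):
        truth, mask, cfg = small_problem()
        state = init_state(truth, mask, cfg)
        for u, r in zip(state.factors, cfg.rank):
            np.testing.assert_allclose(u.T @ u, np.eye(r), atol=1e-12)

    def test_empty_mask_and_excess_rank_rejected(self):
        truth, mask, cfg = small_problem()
        with pytest.raises(ValueError, match="observed"):
            init_state(truth, np.zeros_like(mask), cfg)
        with pytest.raises(ValueError, match="rank"):
            init_state(truth, mask, SolverConfig(rank=(9, 2, 2)))


class TestUpdateAuxiliary:
    def test_zero_weight_gives_no_shrinkage(self):
        truth, mask, _ = small_problem()
        cfg = SolverConfig(rank=(2, 2, 2), alpha=(0.0, 0.5, 0.5), seed=3)
        state = advanced_state(truth, mask, cfg)
        vs = update_auxiliary(state, cfg)
        np.testing.assert_allclose(
            vs[0], state.core + state.multipliers[0] / state.mu, atol=1e-12
        )

    def test_oversized_threshold_zeroes_auxiliary(self):
        truth, mask, cfg = small_problem()
        state = init_state(truth, mask, cfg)
        state.mu = 1e-12  # alpha/mu astronomically above every singular value
        vs = update_auxiliary(state, cfg)
        for v in vs:
            np.testing.assert_array_equal(v, np.zeros(cfg.rank))

    def test_matches_unfold_svt_fold_composition(self):
        truth, mask, cfg = small_problem(shape=(5, 5, 5), rank=(3, 3, 3))
        state = advanced_state(truth, mask, cfg)
        vs = update_auxiliary(state, cfg)
        alpha = cfg.resolved_alpha()
        for i in range(3):
            z = unfold(state.core + state.multipliers[i] / state.mu, i + 1)
            want = fold(svt(z, alpha[i] / state.mu).matrix, i + 1, cfg.rank)
            np.testing.assert_allclose(vs[i], want, atol=1e-12)


class TestUpdateCore:
    def test_vanishing_lambda_collapses_to_consensus_mean(self):
        truth, mask, _ = small_problem()
        cfg = SolverConfig(rank=(2, 2, 2), seed=3, lam=1e-12)
        state = advanced_state(truth, mask, cfg)
        got = update_core(state, cfg)
        want = np.mean(
            [v - y / state.mu for v, y in zip(state.aux, state.multipliers)], axis=0
        )
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_finite_difference_gradient_vanishes_at_update(self, rng):
        truth, mask, cfg = small_problem()
        state = advanced_state(truth, mask, cfg)
        c_star = update_core(state, cfg)

        def objective(c):
            val = 0.0
            for v, y in zip(state.aux, state.multipliers):
                val += 0.5 * state.mu * frobenius_norm(c - v + y / state.mu) ** 2
            rec = multi_mode_product(c, state.factors)
            val += 0.5 * cfg.lam * frobenius_norm(state.x - rec) ** 2
            return val

        eps = 1e-6
        grad = np.zeros_like(c_star)
        for idx in np.ndindex(c_star.shape):
            plus = c_star.copy(); plus[idx] += eps
            minus = c_star.copy(); minus[idx] -= eps
            grad[idx] = (objective(plus) - objective(minus)) / (2 * eps)
        assert np.linalg.norm(grad) < 1e-4  # central-difference noise floor

    def test_fixed_point_when_consistent(self, rng):
        # V_i = C*, Y_i = 0, X = reconstruction  =>  update returns C*
        cfg = SolverConfig(rank=(2, 2, 2), seed=0)
        c_star = rng.standard_normal((2, 2, 2))
        us = [random_orthonormal(rng, d, 2) for d in (6, 7, 5)]
        x = multi_mode_product(c_star, us)
        state = init_state(x, np.ones(x.shape, dtype=bool), cfg)
        state.factors = us
        state.aux = [c_star.copy() for _ in range(3)]
        state.multipliers = [np.zeros_like(c_star) for _ in range(3)]
        np.testing.assert_allclose(update_core(state, cfg), c_star, atol=1e-10)


class TestUpdateFactor:
    def test_returns_orthonormal_columns(self):
        truth, mask, cfg = small_problem()
        state = advanced_state(truth, mask, cfg)
        for i in range(1, 4):
            u = update_factor(state, i, cfg)
            np.testing.assert_allclose(u.T @ u, np.eye(cfg.rank[i - 1]), atol=1e-12)

    def test_least_squares_step_never_increases_objective(self):
        # f(U) = 0.5 || Z x_i U - X ||_F^2 cannot increase at the
        # unconstrained least-squares solution; its thin-QR factor Q
        # attains the same value jointly with the core transformed by R
        for seed in range(4):
            truth, mask, _ = small_problem(seed=seed)
            cfg = SolverConfig(rank=(2, 2, 2), seed=seed)
            state = advanced_state(truth, mask, cfg, sweeps=2)
            for i in range(1, 4):
                def f(u, core=None):
                    trial = list(state.factors)
                    trial[i - 1] = u
                    rec = multi_mode_product(
                        state.core if core is None else core, trial
                    )
                    return 0.5 * frobenius_norm(rec - state.x) ** 2

                before = f(state.factors[i - 1])
                u_tilde = least_squares_factor(state, i)
                after_ls = f(u_tilde)
                assert after_ls <= before * (1 + 1e-10) + 1e-10
                # QR-orthogonalized factor + R-transformed core reproduce
                # the least-squares objective value exactly
                q, r = np.linalg.qr(u_tilde)
                q = q * np.sign(np.diagonal(r))
                r = (np.sign(np.diagonal(r))[:, None]) * r
                from ctnmqr import mode_n_product
                core_t = mode_n_product(state.core, r, i)
                assert f(q, core=core_t) == pytest.approx(after_ls, rel=1e-8, abs=1e-9)
                state.factors[i - 1] = update_factor(state, i, cfg)

    def test_recovers_subspace_on_noiseless_data(self, rng):
        # with true core, other factors at truth, and X exact, the update
        # must span the true mode subspace
        cfg = SolverConfig(rank=(2, 3, 2), seed=1)
        core = rng.standard_normal((2, 3, 2))
        us = [random_orthonormal(rng, d, r) for d, r in [(8, 2), (9, 3), (7, 2)]]
        x = multi_mode_product(core, us)
        state = init_state(x, np.ones(x.shape, dtype=bool), cfg)
        state.core = core
        state.factors = [u.copy() for u in us]
        for i in range(1, 4):
            state.factors[i - 1] = random_orthonormal(rng, us[i - 1].shape[0], us[i - 1].shape[1])
            u_new = update_factor(state, i, cfg)
            p_true = us[i - 1] @ us[i - 1].T
            p_new = u_new @ u_new.T
            assert np.max(np.abs(p_true - p_new)) < 1e-8
            state.factors[i - 1] = us[i - 1].copy()


class TestUpdateCompletionAndDuals:
    def test_fully_observed_returns_data(self):
        truth, _, cfg = small_problem()
        state = advanced_state(truth, np.ones(truth.shape, dtype=bool), cfg)
        np.testing.assert_array_equal(
            update_completion(state, truth, np.ones(truth.shape, dtype=bool)), truth
        )

    def test_observed_kept_and_complement_is_reconstruction(self):
        truth, mask, cfg = small_problem()
        state = advanced_state(truth, mask, cfg)
        x = update_completion(state, truth, mask)
        np.testing.assert_array_equal(x[mask], truth[mask])
        rec = multi_mode_product(state.core, state.factors)
        np.testing.assert_array_equal(x[~mask], rec[~mask])

    def test_multipliers_unchanged_at_consensus(self):
        truth, mask, cfg = small_problem()
        state = init_state(truth, mask, cfg)
        state.aux = [state.core.copy() for _ in range(3)]
        new_y, _ = update_multipliers_and_penalty(state, cfg)
        for y in new_y:
            np.testing.assert_array_equal(y, np.zeros(cfg.rank))

    def test_penalty_schedule_geometric_then_capped(self):
        truth, mask, _ = small_problem()
        cfg = SolverConfig(rank=(2, 2, 2), mu0=1e-3, rho=1.05, mu_max=1.2e-3)
        state = init_state(truth, mask, cfg)
        _, mu1 = update_multipliers_and_penalty(state, cfg)
        state.mu = mu1
        _, mu2 = update_multipliers_and_penalty(state, cfg)
        assert mu1 == pytest.approx(1.05e-3)
        assert mu2 == pytest.approx(1.1025e-3)  # rho^2 * mu0
        state.mu = mu2
        for _ in range(10):
            _, state.mu = update_multipliers_and_penalty(state, cfg)
        assert state.mu == cfg.mu_max


class TestRelativeChange:
    def test_closed_forms(self, rng):
        x = rng.standard_normal((3, 4))
        assert relative_change(x, x) == 0.0
        assert relative_change(2 * x, x) == pytest.approx(1.0)

    def test_agrees_with_elementwise_formula(self, rng):
        a = rng.standard_normal((4, 5, 2))
        b = rng.standard_normal((4, 5, 2))
        want = np.sqrt(((a - b) ** 2).sum()) / np.sqrt((b ** 2).sum())
        assert relative_change(a, b) == pytest.approx(want, rel=1e-14)

    def test_zero_norm_reference_gives_inf_sentinel(self):
        assert relative_change(np.ones((2, 2)), np.zeros((2, 2))) == np.inf


class TestComplete:
    def test_fully_observed_is_immediate(self):
        truth, _, cfg = small_problem()
        res = complete(truth, np.ones(truth.shape, dtype=bool), cfg)
        np.testing.assert_array_equal(res.completed, truth)
        assert res.stop_reason == "tolerance"
        assert res.iterations == 1
        assert res.rel_change_trace[-1] == 0.0

    def test_exact_recovery_small_problem(self):
        truth, mask, cfg = small_problem(seed=11, shape=(20, 20, 20), mr=0.3)
        res = complete(truth, mask, cfg)
        assert rse(res.completed, truth) < 1e-3
        assert res.stop_reason == "tolerance"

    def test_feasibility_trace_length_and_model_invariants(self):
        truth, mask, cfg = small_problem(seed=5, shape=(12, 10, 11))
        res = complete(truth, mask, cfg)
        np.testing.assert_array_equal(res.completed[mask], truth[mask])
        assert len(res.rel_change_trace) == res.iterations
        res.model.validate()

    def test_debug_mode_invariants_hold(self):
        truth, mask, _ = small_problem(seed=2, shape=(10, 10, 10))
        cfg = SolverConfig(rank=(2, 2, 2), seed=2, debug=True, max_iter=60)
        res = complete(truth, mask, cfg)  # debug asserts fire on violation
        assert res.iterations >= 1

    def test_assumption_norm_identity_on_returned_model(self):
        # weighted nuclear norms of core and reconstruction unfoldings agree
        truth, mask, cfg = small_problem(seed=6, shape=(10, 9, 8))
        res = complete(truth, mask, cfg)
        rec = tucker_reconstruct(res.model)
        alpha = cfg.resolved_alpha()
        a = sum(w * np.linalg.svd(unfold(rec, i + 1), compute_uv=False).sum()
                for i, w in enumerate(alpha))
        b = sum(w * np.linalg.svd(unfold(res.model.core, i + 1), compute_uv=False).sum()
                for i, w in enumerate(alpha))
        assert a == pytest.approx(b, rel=1e-6)

    def test_determinism_same_seed_identical_result(self):
        truth, mask, cfg = small_problem(seed=8, shape=(9, 9, 9))
        r1 = complete(truth, mask, cfg)
        r2 = complete(truth, mask, cfg)
        np.testing.assert_array_equal(r1.completed, r2.completed)
        np.testing.assert_array_equal(r1.rel_change_trace, r2.rel_change_trace)
        assert r1.iterations == r2.iterations

    def test_qr_and_hooi_reach_comparable_accuracy(self):
        truth, mask, _ = small_problem(seed=9, shape=(15, 15, 15), rank=(3, 3, 3), mr=0.4)
        cfg = SolverConfig(rank=(3, 3, 3), seed=9)
        r_qr = rse(complete(truth, mask, cfg).completed, truth)
        r_ho = rse(
            complete(truth, mask, SolverConfig(rank=(3, 3, 3), seed=9,
                                               factor_strategy="hooi")).completed,
            truth,
        )
        assert r_qr <= 2 * r_ho and r_ho <= 2 * r_qr

    def test_max_iter_stop_reason(self):
        truth, mask, _ = small_problem(seed=4, shape=(10, 10, 10))
        cfg = SolverConfig(rank=(2, 2, 2), seed=4, max_iter=3)
        res = complete(truth, mask, cfg)
        assert res.stop_reason == "max_iter"
        assert res.iterations == 3


class TestSolverConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rank=(0, 2)),
            dict(rank=(2, 2), alpha=(0.5, 0.6)),
            dict(rank=(2, 2), alpha=(-0.1, 1.1)),
            dict(rank=(2, 2), alpha=(1.0,)),
            dict(rank=(2, 2), lam=-1.0),
            dict(rank=(2, 2), mu0=0.0),
            dict(rank=(2, 2), mu0=2.0, mu_max=1.0),
            dict(rank=(2, 2), rho=1.0),
            dict(rank=(2, 2), rho=1.2),
            dict(rank=(2, 2), tol=0.0),
            dict(rank=(2, 2), max_iter=0),
            dict(rank=(2, 2), factor_strategy="newton"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)

    def test_uniform_alpha_resolution(self):
        assert SolverConfig(rank=(2, 2, 2)).resolved_alpha() == (1 / 3, 1 / 3, 1 / 3)
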
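"""Robinson design assembly, closed-form penalized fits, losses and predictions."""

import numpy as np
import pytest
from scipy.optimize import minimize

import msrlearner as m

from conftest import manual_nuisances, simple_multistudy


class TestEvaluateBasis:
    def test_intercept_only(self):
        basis = m.BasisSpec.intercept(2, 3)
        Vs = m.evaluate_basis(basis, np.random.default_rng(0).standard_normal((5, 3)))
        for Vk in Vs:
            np.testing.assert_allclose(Vk, np.ones((5, 1)))

    def test_linear_with_intercept(self):
        basis = m.BasisSpec.linear(1, 2)
        Vs = m.evaluate_basis(basis, np.array([[2.0, 3.0]]))
        np.testing.assert_allclose(Vs[0], [[1.0, 2.0, 3.0]])

    def test_poly_degree_two_scalar(self):
        basis = m.BasisSpec.poly(1, 1, degree=2)
        Vs = m.evaluate_basis(basis, np.array([[2.0]]))
        np.testing.assert_allclose(Vs[0], [[1.0, 2.0, 4.0]])

    def test_spline_extrapolation_warns(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 1))
        basis = m.BasisSpec.spline_from_data(1, X, n_knots=5)
        with pytest.warns(UserWarning, match="extrapolating"):
            basis.evaluate(np.array([[X.max() + 5.0]]))


def _tiny_dataset(a, y=None, K=2):
    n = len(a)
    return m.MultiStudyDataset(
        y=np.zeros(n) if y is None else np.asarray(y, float),
        a=np.asarray(a), s=np.tile(np.arange(1, K + 1), n // K + 1)[:n],
        X=np.zeros((n, 1)))


class TestBuildDesign:
    def test_intercept_row_formula(self):
        # (1-0.5)*0.6 = 0.30 and (1-0.25)*0.4 = 0.30
        ds = _tiny_dataset([1, 0, 1, 0])
        ns = manual_nuisances(ds, m_k=np.zeros((4, 2)),
                              e_k=np.array([[0.5, 0.25]] * 4),
                              p_k=np.array([[0.6, 0.4]] * 4))
        dm = m.build_design(ds, ns, m.BasisSpec.intercept(2, 1))
        np.testing.assert_allclose(dm.U[0], [0.30, 0.30])

    def test_centered_treatment_zero_row(self):
        # A_i equal to every e_k(X_i) makes the design row vanish
        ds = _tiny_dataset([1, 1, 1, 1])
        ns = manual_nuisances(ds, m_k=np.zeros((4, 2)),
                              e_k=np.full((4, 2), 1.0 - 1e-12),
                              p_k=np.full((4, 2), 0.5))
        dm = m.build_design(ds, ns, m.BasisSpec.intercept(2, 1))
        np.testing.assert_allclose(dm.U, 0.0, atol=1e-10)

    def test_k1_reduces_to_single_study_design(self):
        rng = np.random.default_rng(1)
        n = 30
        X = rng.standard_normal((n, 2))
        a = rng.integers(0, 2, n)
        e = rng.uniform(0.2, 0.8, n)
        ds = m.MultiStudyDataset(y=rng.standard_normal(n), a=a,
                                 s=np.ones(n, int), X=X)
        ns = manual_nuisances(ds, m_k=np.zeros((n, 1)), e_k=e[:, None],
                              p_k=np.ones((n, 1)))
        dm = m.build_design(ds, ns, m.BasisSpec.linear(1, 2))
        V = np.hstack([np.ones((n, 1)), X])
        np.testing.assert_allclose(dm.U, V * (a - e)[:, None])


def random_instance(seed, n=50, K=2, p=2):
    """Small random design + residualized outcome for optimizer cross-checks."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    a = rng.integers(0, 2, n)
    s = rng.integers(1, K + 1, n)
    s[:2 * K] = np.tile(np.arange(1, K + 1), 2)
    y = rng.standard_normal(n) * 2
    ds = m.MultiStudyDataset(y=y, a=a, s=s, X=X)
    e = rng.uniform(0.2, 0.8, (n, K))
    p_raw = rng.uniform(0.1, 1.0, (n, K))
    p_k = p_raw / p_raw.sum(1, keepdims=True)
    ns = manual_nuisances(ds, m_k=rng.standard_normal((n, K)), e_k=e, p_k=p_k)
    return ds, ns


class TestClosedFormFit:
    def test_null_outcome_with_penalty_gives_zero(self):
        ds, ns = random_instance(0)
        ns.m_k_cross[:] = 0.0
        ns.m_pooled[:] = 0.0
        ds.y[:] = 0.0
        fit = m.fit_multistudy_rlearner(ds, ns, m.BasisSpec.linear(2, 2), lam=0.5)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)

    def test_square_nonsingular_interpolates(self):
        rng = np.random.default_rng(3)
        n = 6  # equals stacked dimension d = 2 * (1 + 2)
        X = rng.standard_normal((n, 2))
        ds = m.MultiStudyDataset(y=rng.standard_normal(n), a=rng.integers(0, 2, n),
                                 s=np.array([1, 1, 1, 2, 2, 2]), X=X)
        ns = manual_nuisances(ds, m_k=np.zeros((n, 2)),
                              e_k=rng.uniform(0.2, 0.45, (n, 2)),
                              p_k=np.full((n, 2), 0.5))
        fit = m.fit_multistudy_rlearner(ds, ns, m.BasisSpec.linear(2, 2), lam=0.0)
        dm = m.build_design(ds, ns, m.BasisSpec.linear(2, 2))
        np.testing.assert_allclose(dm.y_tilde - dm.U @ fit.beta, 0.0, atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_minimizer(self, seed):
        ds, ns = random_instance(seed, n=50)
        basis = m.BasisSpec.linear(2, 2)
        lam = 0.1
        fit = m.fit_multistudy_rlearner(ds, ns, basis, lam=lam)
        dm = m.build_design(ds, ns, basis)

        def objective(b):
            r = dm.y_tilde - dm.U @ b
            return np.mean(r**2) + lam * b @ b

        res = minimize(objective, np.zeros(dm.U.shape[1]), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-6)

    def test_objective_descent(self):
        ds, ns = random_instance(7)
        basis = m.BasisSpec.linear(2, 2)
        lam = 0.05
        fit = m.fit_multistudy_rlearner(ds, ns, basis, lam=lam)
        dm = m.build_design(ds, ns, basis)

        def objective(b):
            r = dm.y_tilde - dm.U @ b
            return np.mean(r**2) + lam * b @ b

        best = objective(fit.beta)
        assert best <= objective(np.zeros_like(fit.beta)) + 1e-12
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert best <= objective(rng.standard_normal(fit.beta.size)) + 1e-12


class TestReparameterized:
    def test_lambda_zero_matches_unpenalized_predictions(self):
        ds, ns = random_instance(11)
        basis = m.BasisSpec.linear(2, 2)
        f0 = m.fit_multistudy_rlearner(ds, ns, basis, lam=0.0)
        fr = m.fit_reparameterized(ds, ns, basis, lam_delta=0.0)
        Xnew = np.random.default_rng(1).standard_normal((20, 2))
        np.testing.assert_allclose(m.predict_study_cates(fr, Xnew),
                                   m.predict_study_cates(f0, Xnew), atol=1e-8)

    def test_large_penalty_collapses_deviations(self):
        ds, ns = random_instance(13, n=80)
        fr = m.fit_reparameterized(ds, ns, m.BasisSpec.linear(2, 2), lam_delta=1e9)
        deltas = fr.diagnostics["delta_blocks"]
        assert max(np.linalg.norm(d) for d in deltas) < 1e-3
        b1, b2 = fr.beta_block(1), fr.beta_block(2)
        np.testing.assert_allclose(b1, b2, atol=1e-3)

    def test_moderate_penalty_matches_brute_force(self):
        ds, ns = random_instance(17, n=60)
        basis = m.BasisSpec.linear(2, 2)
        lam_d = 0.3
        fr = m.fit_reparameterized(ds, ns, basis, lam_delta=lam_d)
        dm = m.build_design(ds, ns, basis)
        d0 = basis.dims[0]
        blocks = [dm.U[:, sl] for sl in dm.block_slices]

        def objective(theta):
            tau_c = theta[:d0]
            deltas = [theta[d0 * (k + 1): d0 * (k + 2)] for k in range(2)]
            pred = sum(Bk @ (tau_c + dk) for Bk, dk in zip(blocks, deltas))
            pen = lam_d * sum(dk @ dk for dk in deltas)
            return np.mean((dm.y_tilde - pred) ** 2) + pen

        res = minimize(objective, np.zeros(3 * d0), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 5000})
        tau_c = res.x[:d0]
        expected = np.concatenate([tau_c + res.x[d0 * (k + 1): d0 * (k + 2)]
                                   for k in range(2)])
        np.testing.assert_allclose(fr.beta, expected, atol=1e-5)

    def test_shrinkage_monotone_in_penalty(self):
        ds, ns = random_instance(19, n=80)
        norms = []
        for lam_d in [0.0, 0.1, 1.0, 10.0, 1e3]:
            fr = m.fit_reparameterized(ds, ns, m.BasisSpec.linear(2, 2), lam_delta=lam_d)
            norms.append(sum(np.linalg.norm(d) for d in fr.diagnostics["delta_blocks"]))
        assert all(norms[i + 1] <= norms[i] + 1e-9 for i in range(len(norms) - 1))

    def test_differing_bases_rejected(self):
        ds, ns = random_instance(23)
        basis = m.BasisSpec([m.StudyBasis("linear", 2), m.StudyBasis("intercept", 2)])
        with pytest.raises(ValueError, match="identical bases"):
            m.fit_reparameterized(ds, ns, basis)


class TestPrediction:
    def test_intercept_only_constant(self):
        fit = m.CATEFit(beta=np.array([0.5, 0.5]), basis=m.BasisSpec.intercept(2, 1),
                        membership=None)
        np.testing.assert_allclose(
            m.predict_study_cates(fit, np.zeros((4, 1))), 0.5)

    def test_zero_beta_zero_predictions(self):
        fit = m.CATEFit(beta=np.zeros(6), basis=m.BasisSpec.linear(2, 2),
                        membership=None)
        np.testing.assert_allclose(
            m.predict_study_cates(fit, np.ones((3, 2))), 0.0)

    def test_linear_evaluation(self):
        fit = m.CATEFit(beta=np.array([1.0, 2.0]), basis=m.BasisSpec.linear(1, 1),
                        membership=None)
        np.testing.assert_allclose(
            m.predict_study_cates(fit, np.array([[3.0]])), [[7.0]])

    def test_weighted_combination(self):
        memb = m.MembershipModel(np.array([[np.log(1 / 3)]]),
                                 m.MembershipBasis(m.StudyBasis("intercept", 1)), 2)
        # p = (0.25, 0.75); intercept-only taus (1, 3) -> 2.5
        fit = m.CATEFit(beta=np.array([1.0, 3.0]), basis=m.BasisSpec.intercept(2, 1),
                        membership=memb)
        np.testing.assert_allclose(m.predict_cate(fit, np.zeros((1, 1))), [2.5])

    def test_equal_taus_ignore_weights(self):
        memb = m.MembershipModel(np.array([[1.3]]),
                                 m.MembershipBasis(m.StudyBasis("intercept", 1)), 2)
        fit = m.CATEFit(beta=np.array([0.7, 0.7]), basis=m.BasisSpec.intercept(2, 1),
                        membership=memb)
        np.testing.assert_allclose(m.predict_cate(fit, np.zeros((2, 1))), 0.7)


class TestLosses:
    def test_oracle_loss_zero_at_truth_noiseless(self):
        rng = np.random.default_rng(5)
        n, K = 200, 2
        X = rng.standard_normal((n, 1))
        tau_fns = [lambda X: 1.0 + 0 * X[:, 0], lambda X: -1.0 + 0 * X[:, 0]]
        e = np.array([0.4, 0.6])
        p_fn = lambda X: np.full((np.atleast_2d(X).shape[0], K), 0.5)
        e_fn = lambda X: np.tile(e, (np.atleast_2d(X).shape[0], 1))
        a = rng.integers(0, 2, n)
        s = rng.integers(1, 3, n)
        s[:4] = [1, 1, 2, 2]
        # noiseless outcomes consistent with the transformation at the truth
        mu = np.zeros(n)
        taus = np.column_stack([f(X) for f in tau_fns])
        m_star = mu + (e[None, :] * taus * 0.5).sum(1)
        y = m_star + ((a[:, None] - e[None, :]) * 0.5 * taus).sum(1)
        ds = m.MultiStudyDataset(y=y, a=a, s=s, X=X)
        L = m.oracle_loss(tau_fns, ds, lambda X: m_star[:len(np.atleast_2d(X))], e_fn, p_fn)
        # recompute m_star on the dataset path: pass exact vector
        L = m.oracle_loss(tau_fns, ds, lambda Xq: m_star, e_fn, p_fn)
        assert L < 1e-20

    def test_null_model_loss_is_residual_variance(self):
        ds, ns = random_instance(29)
        zero = [lambda X: np.zeros(np.atleast_2d(X).shape[0])] * 2
        L = m.plug_in_loss(zero, ds, ns)
        np.testing.assert_allclose(L, np.mean((ds.y - ns.m_pooled) ** 2))

    def test_independent_summation_path(self):
        ds, ns = random_instance(31)
        tau_fns = [lambda X: np.atleast_2d(X)[:, 0], lambda X: -np.atleast_2d(X)[:, 1]]
        L = m.plug_in_loss(tau_fns, ds, ns)
        # direct elementwise summation, written independently
        total = 0.0
        for i in range(ds.n):
            drift = 0.0
            for k in range(2):
                tk = ds.X[i, 0] if k == 0 else -ds.X[i, 1]
                drift += (ds.a[i] - ns.e_k_cross[i, k]) * ns.p_cross[i, k] * tk
            total += ((ds.y[i] - ns.m_pooled[i]) - drift) ** 2
        np.testing.assert_allclose(L, total / ds.n, atol=1e-12)

    def test_plug_in_equals_oracle_when_nuisances_are_truths(self):
        ds, ns = random_instance(37)
        tau_fns = [lambda X: np.atleast_2d(X)[:, 0] * 0.5] * 2
        L_hat = m.plug_in_loss(tau_fns, ds, ns)
        L = m.oracle_loss(tau_fns, ds,
                          lambda X: ns.m_pooled, lambda X: ns.e_k_cross,
                          lambda X: ns.p_cross)
        np.testing.assert_allclose(L_hat, L, atol=1e-14)

    def test_fitted_beta_minimizes_plug_in_loss(self):
        ds, ns = random_instance(41)
        basis = m.BasisSpec.linear(2, 2)
        fit = m.fit_multistudy_rlearner(ds, ns, basis, lam=0.0)
        dm = m.build_design(ds, ns, basis)
        best = np.mean((dm.y_tilde - dm.U @ fit.beta) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(10):
            other = fit.beta + rng.standard_normal(fit.beta.size) * 0.1
            assert best <= np.mean((dm.y_tilde - dm.U @ other) ** 2) + 1e-12


class TestRegret:
    def test_zero_at_truth(self):
        X = np.random.default_rng(0).standard_normal((100, 1))
        tau = [lambda X: np.atleast_2d(X)[:, 0]] * 2
        e_fn = lambda X: np.full((np.atleast_2d(X).shape[0], 2), 0.5)
        p_fn = lambda X: np.full((np.atleast_2d(X).shape[0], 2), 0.5)
        assert m.regret(tau, tau, e_fn, p_fn, X) == 0.0

    def test_constant_offset_closed_form(self):
        # e = 0.5, p = 0.5 (K=2), tau_k = tau*_k + 1 -> 2 * (0.25 * 0.25 * 1) = 0.125
        X = np.zeros((10, 1))
        tau_star = [lambda X: np.zeros(np.atleast_2d(X).shape[0])] * 2
        tau = [lambda X: np.ones(np.atleast_2d(X).shape[0])] * 2
        e_fn = lambda X: np.full((np.atleast_2d(X).shape[0], 2), 0.5)
        p_fn = lambda X: np.full((np.atleast_2d(X).shape[0], 2), 0.5)
        np.testing.assert_allclose(m.regret(tau, tau_star, e_fn, p_fn, X), 0.125)


class TestEffectRangeScaling:
    def test_values(self):
        np.testing.assert_allclose(m.scale_to_effect_range(0.0), 0.0)
        np.testing.assert_allclose(m.scale_to_effect_range(np.log(3)), 0.5)
        assert m.scale_to_effect_range(50.0) == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        taus = np.linspace(-20, 20, 101)
        vals = m.scale_to_effect_range(taus)
        assert np.all(np.diff(vals) > 0)
        assert vals.min() > -1 and vals.max() < 1


class TestSelectPenalty:
    def test_singleton_grid(self, two_study):
        folds = m.make_folds(two_study, Q=4, seed=0)
        ns = m.fit_nuisances(two_study, folds,
                             outcome_learner=m.LearnerSpec("regression", "ols", "none"),
                             propensity_learner=m.LearnerSpec("binary-probability",
                                                              "logistic", "none"))
        lam = m.select_penalty(two_study, ns, m.BasisSpec.linear(2, 3), [0.7], folds)
        assert lam == 0.7

    def test_pure_noise_prefers_largest(self):
        # small smooth penalties all overfit noise; the heavy penalty should win
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 500)
            n, p = 40, 8
            X = rng.standard_normal((n, p))
            a = rng.integers(0, 2, n)
            s = rng.integers(1, 3, n)
            s[:4] = [1, 1, 2, 2]
            ds = m.MultiStudyDataset(y=rng.standard_normal(n), a=a, s=s, X=X)
            ns = manual_nuisances(ds, m_k=np.zeros((n, 2)),
                                  e_k=np.full((n, 2), 0.5), p_k=np.full((n, 2), 0.5))
            folds = m.make_folds(ds, Q=4, seed=seed)
            lam = m.select_penalty(ds, ns, m.BasisSpec.linear(2, p),
                                   [1e-4, 1e-3, 1e-2, 10.0], folds)
            wins += lam == 10.0
        assert wins >= 16

    def test_strong_signal_prefers_small(self):
        rng_master = np.random.default_rng(0)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            X = rng.standard_normal((n, 2))
            a = rng.integers(0, 2, n)
            s = rng.integers(1, 3, n)
            s[:4] = [1, 1, 2, 2]
            tau = 3.0 * X[:, 0]
            y = (a - 0.5) * tau + rng.normal(0, 0.05, n)
            ds = m.MultiStudyDataset(y=y, a=a, s=s, X=X)
            ns = manual_nuisances(ds, m_k=np.zeros((n, 2)),
                                  e_k=np.full((n, 2), 0.5), p_k=np.full((n, 2), 0.5))
            folds = m.make_folds(ds, Q=4, seed=seed)
            lam = m.select_penalty(ds, ns, m.BasisSpec.linear(2, 2),
                                   [0.001, 0.01, 0.1, 1.0, 10.0], folds)
            wins += lam < 0.1
        assert wins >= 16


class TestParameterRecovery:
    def test_scenario_a_known_nuisances(self):
        # linear truths, oracle nuisances, lam -> 0: stacked coefficients recovered.
        # Well-separated studies keep the block design conditioned; averaging the
        # unbiased estimate over 5 data draws removes most of the sampling noise.
        cfg = m.ScenarioConfig(K=2, p=4, q=2, n_k=(5000, 5000), sigma_tau=0.5,
                               covariate_shift=3.0, seed=3)
        pop = m.make_population(cfg)
        truth = m.make_truth_scenario_a(cfg, 42, population=pop)
        betas = []
        for r in range(5):
            X, S = m.sample_covariates(cfg, 4200 + r, population=pop)
            A, Y, _, _ = m.generate_outcomes(truth, X, S, 8400 + r)
            ds = m.MultiStudyDataset(y=Y, a=A, s=S, X=X)
            ns = m.nuisances_from_truth(ds, truth.m_k, truth.e_k, truth.p_star)
            fit = m.fit_multistudy_rlearner(ds, ns, m.BasisSpec.linear(2, 4), lam=0.0)
            betas.append(fit.beta)
        bbar = np.mean(betas, axis=0)
        beta, eta = truth.params["beta"], truth.params["eta"]
        for k in (1, 2):
            expected = np.concatenate([[0.0], beta])
            expected[1:1 + cfg.q] += eta[k - 1]
            block = bbar[fit.block_slices[k - 1]]
            assert np.max(np.abs(block - expected)) < 0.1
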
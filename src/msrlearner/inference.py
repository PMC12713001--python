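"""Sandwich-variance inference for the membership-weighted CATE.

The stacked parameter is theta = (beta, gamma): series coefficients of the
study-specific CATEs and coefficients of the multinomial membership model
(reference category K). Each block solves its own empirical estimating equation:

- beta-block:  psi_beta(w_i) = -2 u_i(gamma) {ytilde_i - u_i(gamma)' beta} + 2 lam P beta,
  the gradient of the (penalized) plug-in R-loss with the design built from the
  parametric membership model p(k | x; gamma);
- gamma-block: the multinomial log-likelihood score
  psi_gamma_j(w_i) = {1(s_i = j) - p(j | x_i; gamma)} v~(x_i), j = 1..K-1,
  which is exactly zeroed by the full-data membership MLE.

With A = d(mean psi)/d theta and B = mean(psi psi'), the asymptotic variance of
tau(x) = g(beta, gamma) = sum_k p(k|x; gamma) v_k(x)' beta_k is

    Var{tau(x)} ~= Dg A^{-1} B A^{-T} Dg' / n.

Because the gamma score does not involve beta, A is block lower-triangular (not
symmetric); the general A^{-1} B A^{-T} form is used. Nuisances m and e_k are
treated as known (Neyman orthogonality), a finite-n approximation.

For exact self-consistency of the estimating equations, the beta reported here
re-solves the R-loss normal equations on the design built with the full-data
membership model p(k | x; gamma_hat); it differs from a fit against cross-fitted
membership probabilities only through p_hat_cross vs p(gamma_hat), both of which
estimate the same truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import BasisSpec
from .data import MultiStudyDataset
from .estimator import CATEFit, _solve_penalized, design_from_parts
from .nuisance import MembershipModel, NuisanceSet

FD_REL_STEP = 1e-5
PSD_TOL = -1e-10


@dataclass
class StackedScore:
    """Per-sample stacked scores and the empirical sandwich components."""

    beta: np.ndarray
    gamma: np.ndarray  # (K-1, d_tilde)
    psi: np.ndarray  # (n, dim_theta)
    A_hat: np.ndarray
    B_hat: np.ndarray
    n: int
    basis: BasisSpec
    membership: MembershipModel
    d_beta: int = 0
    d_gamma: int = 0
    convention: str = "stacked"
    theta_cov: np.ndarray = field(default=None)  # A^{-1} B A^{-T} (unscaled by 1/n)

    def validate(self) -> None:
        if np.max(np.abs(self.B_hat - self.B_hat.T)) > 1e-8:
            raise ValueError("B_hat must be symmetric")
        ev = np.linalg.eigvalsh((self.B_hat + self.B_hat.T) / 2)
        if ev.min() < -1e-6 * max(1.0, ev.max()):
            raise ValueError("B_hat must be positive semidefinite")


def _design_at_gamma(dataset, nuisances, basis, membership, gamma):
    V = membership.basis.evaluate(dataset.X)
    p = MembershipModel.proba_from_gamma(V, gamma)
    Vs = basis.evaluate(dataset.X)
    U = design_from_parts(dataset.a, nuisances.e_k_cross, p, Vs)
    return U, p, V


def stacked_scores(fit: CATEFit, dataset: MultiStudyDataset, nuisances: NuisanceSet,
                   convention: str = "stacked", ddof_correction: bool = True) -> StackedScore:
    """Assemble stacked estimating-equation scores and the empirical A, B matrices.

    ``convention="stacked"`` (default) uses the multinomial log-likelihood score for
    gamma — the equation the membership MLE actually solves. ``convention="loss"``
    instead uses the gradient of the R-loss with respect to gamma (the literal
    derivative of the squared-error criterion), exposed for sensitivity comparison;
    the membership MLE does not zero that equation in finite samples.

    ``ddof_correction`` rescales B by n / (n - dim theta), the standard HC1-style
    degrees-of-freedom adjustment for plug-in score covariances.
    """
    K = dataset.K
    if K == 1:
        # single-study reduction: no membership parameters, beta-block only
        from .basis import MembershipBasis
        membership = fit.membership or MembershipModel(
            np.zeros((0, dataset.p + 1)), MembershipBasis.linear(dataset.p), 1)
        gamma = np.zeros((0, membership.basis.dim))
    else:
        if (fit.membership is None or fit.membership.K != dataset.K
                or fit.membership.gamma.size == 0):
            raise ValueError("inference requires a fitted multinomial membership model")
        membership = fit.membership
        gamma = membership.gamma
    d_t = membership.basis.dim
    d_gamma = (K - 1) * d_t

    U, p_model, V = _design_at_gamma(dataset, nuisances, fit.basis, membership, gamma)
    y_t = dataset.y - nuisances.m_pooled
    n, d_beta = U.shape
    lam, P = fit.lam, fit.P
    Pm = np.eye(d_beta) if (lam > 0 and P is None) else P
    beta = _solve_penalized(U, y_t, lam, Pm)

    def psi_beta_at(Umat, b):
        resid = y_t - Umat @ b
        psi = -2.0 * Umat * resid[:, None]
        if lam > 0:
            psi = psi + 2.0 * lam * (Pm @ b)[None, :]
        return psi

    psi_b = psi_beta_at(U, beta)

    # gamma-block scores
    S_ind = np.zeros((n, K))
    S_ind[np.arange(n), dataset.s - 1] = 1.0
    if convention == "stacked":
        psi_g = np.hstack([
            (S_ind[:, j] - p_model[:, j])[:, None] * V for j in range(K - 1)
        ]) if K > 1 else np.zeros((n, 0))
    elif convention == "loss":
        psi_g = _loss_gradient_gamma(dataset, nuisances, fit.basis, membership,
                                     gamma, beta, y_t)
    else:
        raise ValueError(f"unknown convention {convention!r}")

    psi = np.hstack([psi_b, psi_g])
    dim = d_beta + d_gamma
    B = psi.T @ psi / n
    if ddof_correction and n > dim:
        B = B * (n / (n - dim))

    # A = d(mean psi)/d theta
    A = np.zeros((dim, dim))
    A[:d_beta, :d_beta] = 2.0 * U.T @ U / n + (2.0 * lam * Pm if lam > 0 else 0.0)

    gamma_flat = gamma.ravel()

    def mean_psi_beta(gf):
        Ug, _, _ = _design_at_gamma(dataset, nuisances, fit.basis, membership,
                                    gf.reshape(K - 1, d_t))
        return psi_beta_at(Ug, beta).mean(axis=0)

    def mean_psi_gamma(gf):
        if convention == "stacked":
            pg = MembershipModel.proba_from_gamma(V, gf.reshape(K - 1, d_t))
            return np.hstack([
                (S_ind[:, j] - pg[:, j])[:, None] * V for j in range(K - 1)
            ]).mean(axis=0)
        return _loss_gradient_gamma(dataset, nuisances, fit.basis, membership,
                                    gf.reshape(K - 1, d_t), beta, y_t).mean(axis=0)

    for j in range(d_gamma):
        h = FD_REL_STEP * max(1.0, abs(gamma_flat[j]))
        gp, gm = gamma_flat.copy(), gamma_flat.copy()
        gp[j] += h
        gm[j] -= h
        A[:d_beta, d_beta + j] = (mean_psi_beta(gp) - mean_psi_beta(gm)) / (2 * h)
        A[d_beta:, d_beta + j] = (mean_psi_gamma(gp) - mean_psi_gamma(gm)) / (2 * h)
        if convention == "loss":
            # the loss-gradient gamma equation also involves beta
            pass
    if convention == "loss":
        for j in range(d_beta):
            h = FD_REL_STEP * max(1.0, abs(beta[j]))
            bp, bm = beta.copy(), beta.copy()
            bp[j] += h
            bm[j] -= h
            gp_mean = _loss_gradient_gamma(dataset, nuisances, fit.basis, membership,
                                           gamma, bp, y_t).mean(axis=0)
            gm_mean = _loss_gradient_gamma(dataset, nuisances, fit.basis, membership,
                                           gamma, bm, y_t).mean(axis=0)
            A[d_beta:, j] = (gp_mean - gm_mean) / (2 * h)

    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular A_hat: increase the sample size or reduce the basis dimension"
        )
    Ainv = np.linalg.inv(A)
    theta_cov = Ainv @ B @ Ainv.T
    out = StackedScore(beta=beta, gamma=gamma, psi=psi, A_hat=A, B_hat=B, n=n,
                       basis=fit.basis, membership=membership, d_beta=d_beta,
                       d_gamma=d_gamma, convention=convention, theta_cov=theta_cov)
    out.validate()
    return out


def _loss_gradient_gamma(dataset, nuisances, basis, membership, gamma, beta, y_t):
    """Per-sample gradient of the R-loss criterion h_i with respect to gamma (FD)."""
    K = membership.K
    d_t = membership.basis.dim
    gamma_flat = gamma.ravel()

    def h_vec(gf):
        Ug, _, _ = _design_at_gamma(dataset, nuisances, basis, membership,
                                    gf.reshape(K - 1, d_t))
        return (y_t - Ug @ beta) ** 2

    out = np.empty((dataset.n, gamma_flat.size))
    for j in range(gamma_flat.size):
        h = FD_REL_STEP * max(1.0, abs(gamma_flat[j]))
        gp, gm = gamma_flat.copy(), gamma_flat.copy()
        gp[j] += h
        gm[j] -= h
        out[:, j] = (h_vec(gp) - h_vec(gm)) / (2 * h)
    return out


# -- delta-method pieces ---------------------------------------------------

def _dg_rows(scores: StackedScore, X: np.ndarray):
    """Gradient rows of g(beta, gamma) = sum_k p(k|x;gamma) v_k(x)' beta_k at each x.

    beta-part: p(k|x) v_k(x). gamma-part for block j: p_j(x){tau_j(x) - taubar(x)} v~(x),
    the multinomial derivative of the membership weights.
    """
    X = np.atleast_2d(X)
    m = X.shape[0]
    memb = scores.membership
    K = memb.K
    p = memb.predict_proba(X)  # (m, K)
    Vt = memb.basis.evaluate(X)  # (m, d_t)
    Vs = scores.basis.evaluate(X)
    taus = np.column_stack([
        Vk @ scores.beta[scores.basis.block_slices[k]] for k, Vk in enumerate(Vs)
    ])
    tau_bar = np.einsum("nk,nk->n", taus, p)
    Dg = np.zeros((m, scores.d_beta + scores.d_gamma))
    for k, (Vk, sl) in enumerate(zip(Vs, scores.basis.block_slices)):
        Dg[:, sl] = p[:, k][:, None] * Vk
    d_t = memb.basis.dim
    for j in range(K - 1):
        w = p[:, j] * (taus[:, j] - tau_bar)
        Dg[:, scores.d_beta + j * d_t: scores.d_beta + (j + 1) * d_t] = w[:, None] * Vt
    return Dg, tau_bar


def variance_of_cate(scores: StackedScore, fit: CATEFit, x: np.ndarray) -> np.ndarray:
    """Delta-method sandwich variance of tau(x); vectorized over rows of x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    Dg, _ = _dg_rows(scores, x)
    var = np.einsum("md,de,me->m", Dg, scores.theta_cov, Dg) / scores.n
    if var.min() < PSD_TOL:
        raise ValueError(f"negative variance {var.min()} beyond tolerance")
    return np.maximum(var, 0.0)


@dataclass
class CATEInterval:
    """Wald interval for the CATE at a single covariate vector."""

    x: np.ndarray
    tau_hat: float
    variance: float
    level: float
    lower: float
    upper: float


def confidence_interval(fit: CATEFit, scores: StackedScore, x: np.ndarray,
                        level: float = 0.95) -> CATEInterval:
    """z-based Wald interval tau(x) +/- z_{(1+level)/2} sqrt(Var)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    Dg, tau = _dg_rows(scores, x)
    var = variance_of_cate(scores, fit, x)
    z = stats.norm.ppf((1 + level) / 2)
    half = z * np.sqrt(var)
    return CATEInterval(x=x[0], tau_hat=float(tau[0]), variance=float(var[0]), level=level,
                        lower=float(tau[0] - half[0]), upper=float(tau[0] + half[0]))


def interval_table(fit: CATEFit, scores: StackedScore, X: np.ndarray,
                   level: float = 0.95):
    """Vectorized Wald intervals: (tau_hat, se, lower, upper) arrays over rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, tau = _dg_rows(scores, X)
    var = variance_of_cate(scores, fit, X)
    z = stats.norm.ppf((1 + level) / 2)
    se = np.sqrt(var)
    return tau, se, tau - z * se, tau + z * se


def test_zero_ate(fit: CATEFit, scores: StackedScore, X_eval: np.ndarray):
    """Two-sided z-test of H0: mean_{x in X_eval} tau(x) = 0 via the delta method."""
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    if X_eval.shape[0] == 0:
        raise ValueError("X_eval must be nonempty")
    Dg, tau = _dg_rows(scores, X_eval)
    dbar = Dg.mean(axis=0)
    var = float(dbar @ scores.theta_cov @ dbar) / scores.n
    mean_tau = float(tau.mean())
    if var <= 0:
        return (0.0, 1.0) if mean_tau == 0 else (np.inf * np.sign(mean_tau), 0.0)
    z = mean_tau / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def efficiency_threshold(c: float) -> float:
    """Between-study heterogeneity transition point (1+c) / (2 sqrt(c)).

    For two studies whose propensity variances satisfy e1(1-e1) = c * e2(1-e2),
    the pooled multi-study fit beats the ensembled study-specific fits once the
    error variance exceeds this threshold. Symmetric in c <-> 1/c; equals 1 at c=1.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    return (1.0 + c) / (2.0 * np.sqrt(c))


def bootstrap_variance(fit: CATEFit, dataset: MultiStudyDataset, nuisances: NuisanceSet,
                       x: np.ndarray, n_boot: int = 200, seed: int = 0) -> np.ndarray:
    """Within-study nonparametric bootstrap variance of tau(x) (sensitivity check).

    Patients are resampled with replacement within their study; per-row cross-fitted
    nuisance values travel with the rows (nuisances are not refit), the membership
    model and the R-loss solve are refit on each resample.
    """
    from sklearn.linear_model import LogisticRegression

    from .nuisance import _gamma_from_sklearn

    rng = np.random.default_rng(seed)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    Vs_x = fit.basis.evaluate(x)
    V_all = fit.membership.basis.evaluate(dataset.X)
    Vs_all = fit.basis.evaluate(dataset.X)
    K = dataset.K
    taus = np.empty((n_boot, x.shape[0]))
    idx_by_study = [dataset.study_index(k) for k in range(1, K + 1)]
    for b in range(n_boot):
        rows = np.concatenate([rng.choice(idx, size=idx.size, replace=True)
                               for idx in idx_by_study])
        lr = LogisticRegression(C=np.inf, fit_intercept=False, max_iter=300)
        lr.fit(V_all[rows], dataset.s[rows])
        gamma_b = _gamma_from_sklearn(lr, K, fit.membership.basis.dim)
        p_b = MembershipModel.proba_from_gamma(V_all[rows], gamma_b)
        U_b = design_from_parts(dataset.a[rows], nuisances.e_k_cross[rows], p_b,
                                [Vk[rows] for Vk in Vs_all])
        y_t = dataset.y[rows] - nuisances.m_pooled[rows]
        beta_b = _solve_penalized(U_b, y_t, fit.lam, fit.P)
        p_x = MembershipModel.proba_from_gamma(fit.membership.basis.evaluate(x), gamma_b)
        tk = np.column_stack([Vk @ beta_b[sl] for Vk, sl in zip(Vs_x, fit.basis.block_slices)])
        taus[b] = np.einsum("nk,nk->n", tk, p_x)
    return taus.var(axis=0, ddof=1)
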
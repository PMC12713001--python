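"""Multi-study R-learner: Robinson design, penalized closed-form fit, prediction, losses.

The residual-on-residual regression uses, for each pooled sample i, the stacked row

    u_i = ( {A_i - e_1(X_i)} p(1|X_i) v_1(X_i), ..., {A_i - e_K(X_i)} p(K|X_i) v_K(X_i) )

and the residualized outcome ytilde_i = Y_i - m(X_i), with cross-fitted nuisances.
The penalized series estimate solves the ridge-type normal equations

    (U'U/n + lambda * P) beta = U'ytilde / n,

so study-specific CATEs are tau_k(x) = v_k(x)' beta_k and the patient-level CATE is
the membership-weighted combination tau(x) = sum_k tau_k(x) p(k|x). With K=1 and
p == 1 this is exactly the single-study R-learner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .basis import BasisSpec
from .data import FoldAssignment, MultiStudyDataset
from .nuisance import MembershipModel, NuisanceSet


@dataclass
class DesignMatrix:
    """Stacked Robinson design U (n, d) and residualized outcome ytilde (n,)."""

    U: np.ndarray
    y_tilde: np.ndarray
    block_slices: list

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.y_tilde))):
            raise ValueError("non-finite design entries")


@dataclass
class CATEFit:
    """Fitted multi-study R-learner: stacked coefficients plus everything needed to predict."""

    beta: np.ndarray  # (d,)
    basis: BasisSpec
    membership: MembershipModel | None
    lam: float = 0.0
    P: np.ndarray | None = None
    reparameterized: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def block_slices(self) -> list:
        return self.basis.block_slices

    def beta_block(self, k: int) -> np.ndarray:
        """Coefficients for study k (1-based)."""
        return self.beta[self.block_slices[k - 1]]


def build_design(dataset: MultiStudyDataset, nuisances: NuisanceSet,
                 basis: BasisSpec) -> DesignMatrix:
    """Assemble the multi-study Robinson design from cross-fitted nuisances."""
    if basis.K != dataset.K:
        raise ValueError("basis must define one family per study")
    Vs = basis.evaluate(dataset.X)
    U = design_from_parts(dataset.a, nuisances.e_k_cross, nuisances.p_cross, Vs)
    dm = DesignMatrix(U=U, y_tilde=dataset.y - nuisances.m_pooled,
                      block_slices=basis.block_slices)
    dm.validate()
    return dm


def design_from_parts(a: np.ndarray, e: np.ndarray, p: np.ndarray, Vs: list) -> np.ndarray:
    """Rows u_i from treatment a (n,), propensities e (n,K), memberships p (n,K), bases Vs."""
    cols = []
    for k, Vk in enumerate(Vs):
        w = (a - e[:, k]) * p[:, k]
        cols.append(Vk * w[:, None])
    return np.hstack(cols)


def _solve_penalized(U: np.ndarray, y: np.ndarray, lam: float,
                     P: np.ndarray | None) -> np.ndarray:
    """Minimize (1/n)||y - U b||^2 + lam b'Pb by the symmetric normal equations."""
    n, d = U.shape
    G = U.T @ U / n
    r = U.T @ y / n
    if lam < 0:
        raise ValueError("penalty weight must be >= 0")
    if lam > 0:
        Pm = np.eye(d) if P is None else np.asarray(P, dtype=float)
        if Pm.shape != (d, d):
            raise ValueError("penalty matrix must be d x d")
        if np.max(np.abs(Pm - Pm.T)) > 1e-10:
            raise ValueError("penalty matrix must be symmetric")
        G = G + lam * Pm
    try:
        beta = np.linalg.solve(G, r)
        # reject solutions from numerically singular systems
        if not np.all(np.isfinite(beta)) or np.linalg.cond(G) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular design; returning minimum-norm solution")
        beta = np.linalg.pinv(G) @ r
    return beta


def fit_multistudy_rlearner(dataset: MultiStudyDataset, nuisances: NuisanceSet,
                            basis: BasisSpec, lam: float = 0.0,
                            P: np.ndarray | None = None) -> CATEFit:
    """Step 3: minimize the penalized plug-in multi-study R-loss in closed form."""
    dm = build_design(dataset, nuisances, basis)
    beta = _solve_penalized(dm.U, dm.y_tilde, lam, P)
    resid = dm.y_tilde - dm.U @ beta
    fit = CATEFit(beta=beta, basis=basis, membership=nuisances.membership, lam=lam, P=P,
                  diagnostics={"plug_in_loss": float(np.mean(resid**2))})
    return fit


def fit_reparameterized(dataset: MultiStudyDataset, nuisances: NuisanceSet,
                        basis: BasisSpec, lam_delta: float = 0.0) -> CATEFit:
    """Fit tau_k = tau + delta_k with a squared-l2 penalty on the delta blocks only.

    Requires a common basis v across studies. As lam_delta grows the study deviations
    shrink to zero and the fit approaches a common-CATE model. The returned fit is in
    the standard blocked form beta_k = tau + delta_k.
    """
    if not basis.common():
        raise ValueError("reparameterized fit requires identical bases across studies")
    dm = build_design(dataset, nuisances, basis)
    K = dataset.K
    d0 = basis.dims[0]
    blocks = [dm.U[:, sl] for sl in dm.block_slices]
    U_aug = np.hstack([sum(blocks)] + blocks)  # columns: [tau | delta_1 .. delta_K]
    P = np.eye((K + 1) * d0)
    P[:d0, :d0] = 0.0  # tau block unpenalized
    n = dm.U.shape[0]
    G = U_aug.T @ U_aug / n + lam_delta * P
    r = U_aug.T @ dm.y_tilde / n
    theta = np.linalg.pinv(G) @ r  # singular by construction at lam_delta=0: minimum norm
    tau_c = theta[:d0]
    beta = np.concatenate([tau_c + theta[(k + 1) * d0:(k + 2) * d0] for k in range(K)])
    resid = dm.y_tilde - dm.U @ beta
    return CATEFit(beta=beta, basis=basis, membership=nuisances.membership,
                   lam=lam_delta, P=P, reparameterized=True,
                   diagnostics={
                       "plug_in_loss": float(np.mean(resid**2)),
                       "tau_block": tau_c,
                       "delta_blocks": [theta[(k + 1) * d0:(k + 2) * d0] for k in range(K)],
                   })


# -- prediction -----------------------------------------------------------

def predict_study_cates(fit: CATEFit, Xnew: np.ndarray) -> np.ndarray:
    """Matrix of study-specific CATEs tau_k(x) = v_k(x)' beta_k, shape (rows, K)."""
    Vs = fit.basis.evaluate(Xnew)
    return np.column_stack([Vk @ fit.beta_block(k + 1) for k, Vk in enumerate(Vs)])


def predict_cate(fit: CATEFit, Xnew: np.ndarray) -> np.ndarray:
    """Membership-weighted CATE tau(x) = sum_k tau_k(x) p(k|x) (full-data membership)."""
    taus = predict_study_cates(fit, Xnew)
    if fit.membership is None:
        raise ValueError("fit carries no membership model; use predict_study_cates")
    p = fit.membership.predict_proba(np.atleast_2d(Xnew))
    return np.einsum("nk,nk->n", taus, p)


def scale_to_effect_range(tau_values: np.ndarray) -> np.ndarray:
    """Map effects onto [-1, 1] via 2*expit(tau) - 1 (binary-outcome reporting scale)."""
    return 2.0 * expit(np.asarray(tau_values, dtype=float)) - 1.0


# -- losses ---------------------------------------------------------------

def _tau_matrix(tau_functions, X: np.ndarray, K: int) -> np.ndarray:
    """Evaluate candidate CATEs as an (n, K) matrix from a callable or list of callables."""
    X = np.atleast_2d(X)
    if callable(tau_functions):
        out = np.asarray(tau_functions(X), dtype=float)
        if out.ndim == 1:
            out = np.tile(out[:, None], (1, K))
        return out
    return np.column_stack([np.asarray(f(X), dtype=float) for f in tau_functions])


def oracle_loss(tau_functions, dataset: MultiStudyDataset, m_star, e_star, p_star) -> float:
    """Oracle multi-study R-loss with known nuisance functions.

    ``m_star(X) -> (n,)``, ``e_star(X) -> (n, K)``, ``p_star(X) -> (n, K)``.
    """
    X = dataset.X
    taus = _tau_matrix(tau_functions, X, dataset.K)
    e = np.asarray(e_star(X), dtype=float)
    p = np.asarray(p_star(X), dtype=float)
    drift = ((dataset.a[:, None] - e) * p * taus).sum(axis=1)
    resid = (dataset.y - np.asarray(m_star(X), dtype=float)) - drift
    return float(np.mean(resid**2))


def plug_in_loss(tau_functions, dataset: MultiStudyDataset, nuisances: NuisanceSet) -> float:
    """Plug-in multi-study R-loss with cross-fitted nuisances (model-selection criterion)."""
    taus = _tau_matrix(tau_functions, dataset.X, dataset.K)
    drift = ((dataset.a[:, None] - nuisances.e_k_cross) * nuisances.p_cross * taus).sum(axis=1)
    resid = (dataset.y - nuisances.m_pooled) - drift
    return float(np.mean(resid**2))


def regret(tau_functions, tau_star_fn, e_star, p_star, X_sample: np.ndarray) -> float:
    """Overlap-weighted excess-risk functional, Monte-Carlo averaged over X_sample:

        mean_x sum_k e_k(x){1 - e_k(x)} p(k|x)^2 {tau*_k(x) - tau_k(x)}^2.

    Note: this diagonal form coincides with the population loss difference
    L(tau) - L(tau*) exactly when memberships partition the covariate space
    (p(k|x) in {0,1}); with overlapping memberships it omits cross-study
    covariance terms and should be read as an overlap-weighted MSE summary.
    """
    X = np.atleast_2d(X_sample)
    e = np.asarray(e_star(X), dtype=float)
    p = np.asarray(p_star(X), dtype=float)
    K = e.shape[1]
    taus = _tau_matrix(tau_functions, X, K)
    tstar = _tau_matrix(tau_star_fn, X, K)
    return float(np.mean((e * (1 - e) * p**2 * (tstar - taus) ** 2).sum(axis=1)))


# -- penalty selection ----------------------------------------------------

def select_penalty(dataset: MultiStudyDataset, nuisances: NuisanceSet, basis: BasisSpec,
                   lam_grid, folds: FoldAssignment, P: np.ndarray | None = None) -> float:
    """Cross-validated plug-in R-loss over a penalty grid; ties go to the larger penalty."""
    lam_grid = list(lam_grid)
    if not lam_grid:
        raise ValueError("empty penalty grid")
    dm = build_design(dataset, nuisances, basis)
    scores = np.zeros(len(lam_grid))
    for q in range(1, folds.Q + 1):
        held = folds.pooled_fold == q
        train = ~held
        for j, lam in enumerate(lam_grid):
            beta = _solve_penalized(dm.U[train], dm.y_tilde[train], lam, P)
            resid = dm.y_tilde[held] - dm.U[held] @ beta
            scores[j] += float(np.sum(resid**2))
    best = np.min(scores)
    winners = [lam for lam, s in zip(lam_grid, scores) if s <= best * (1 + 1e-12)]
    return float(max(winners))
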
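"""Reference estimators: the study-specific R-learner ensemble and the pooled R-learner.

The study-specific comparator fits a plain single-study R-learner inside each study,

    beta_k^R = argmin_b (1/n_k) sum_{i in study k} [ {Y_i - m_k(X_i)} - {A_i - e_k(X_i)} v_k(X_i)' b ]^2,

then ensembles predictions with membership weights: tau^SS(x) = sum_k p(k|x) v_k(x)' beta_k^R.
(The 1/p(k|x) rescaling of the multi-study design rows cancels the membership factor
analytically, leaving exactly this within-study design — no division by small
probabilities ever happens numerically.)

The pooled comparator ignores study labels entirely: a single-study R-learner on the
pooled data with pooled nuisances m(x) = E[Y|x], e(x) = pr(A=1|x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec, StudyBasis
from .data import FoldAssignment, MultiStudyDataset
from .estimator import _solve_penalized
from .learners import LearnerSpec
from .nuisance import MembershipModel, NuisanceSet, clip_probabilities


@dataclass
class StudySpecificFit:
    """Per-study R-learner coefficients plus the membership model used for ensembling."""

    betas: list  # K arrays, beta_k^R of length d_k
    basis: BasisSpec
    membership: MembershipModel | None
    lam: float = 0.0
    in_sample_loss: list = field(default_factory=list)


def fit_study_specific_rlearner(dataset: MultiStudyDataset, nuisances: NuisanceSet,
                                basis: BasisSpec, lam: float = 0.0,
                                P_blocks: list | None = None) -> StudySpecificFit:
    """Fit a within-study R-learner in every study (no cross-study borrowing)."""
    Vs = basis.evaluate(dataset.X)
    betas, losses = [], []
    for k in range(1, dataset.K + 1):
        idx = dataset.study_index(k)
        d_k = basis.dims[k - 1]
        if idx.size <= d_k:
            raise ValueError(f"study {k}: n_k={idx.size} too small for basis dim {d_k}")
        Uk = Vs[k - 1][idx] * (dataset.a[idx] - nuisances.e_k_cross[idx, k - 1])[:, None]
        y_t = dataset.y[idx] - nuisances.m_k_cross[idx, k - 1]
        Pk = None if P_blocks is None else P_blocks[k - 1]
        beta_k = _solve_penalized(Uk, y_t, lam, Pk)
        betas.append(beta_k)
        losses.append(float(np.mean((y_t - Uk @ beta_k) ** 2)))
    return StudySpecificFit(betas=betas, basis=basis, membership=nuisances.membership,
                            lam=lam, in_sample_loss=losses)


def predict_study_specific(fit: StudySpecificFit, Xnew: np.ndarray,
                           membership: MembershipModel | None = None) -> np.ndarray:
    """Ensembled prediction tau^SS(x) = sum_k p(k|x) v_k(x)' beta_k^R."""
    memb = membership or fit.membership
    if memb is None:
        raise ValueError("no membership model available for ensembling")
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    Vs = fit.basis.evaluate(Xnew)
    taus = np.column_stack([Vk @ b for Vk, b in zip(Vs, fit.betas)])
    p = memb.predict_proba(Xnew)
    return np.einsum("nk,nk->n", taus, p)


def predict_study_specific_cates(fit: StudySpecificFit, Xnew: np.ndarray) -> np.ndarray:
    """Per-study predictions v_k(x)' beta_k^R, shape (rows, K)."""
    Vs = fit.basis.evaluate(np.atleast_2d(Xnew))
    return np.column_stack([Vk @ b for Vk, b in zip(Vs, fit.betas)])


@dataclass
class PooledFit:
    """Single-study R-learner on the pooled data (study labels ignored)."""

    beta: np.ndarray
    basis: StudyBasis
    lam: float = 0.0
    in_sample_loss: float = 0.0


def fit_pooled_nuisances(dataset: MultiStudyDataset, folds: FoldAssignment,
                         outcome_learner: LearnerSpec | None = None,
                         propensity_learner: LearnerSpec | None = None,
                         clip: tuple = (0.01, 0.99)):
    """Cross-fitted pooled nuisances m(x), e(x) fit ignoring study labels."""
    outcome_learner = outcome_learner or LearnerSpec("regression", "elastic-net", "spline")
    propensity_learner = propensity_learner or LearnerSpec("binary-probability", "logistic",
                                                           "spline")
    n = dataset.n
    m_hat = np.empty(n)
    e_hat = np.empty(n)
    for q in range(1, folds.Q + 1):
        held = np.flatnonzero(folds.pooled_fold == q)
        train = np.flatnonzero(folds.pooled_fold != q)
        m_hat[held] = outcome_learner.build().fit(
            dataset.X[train], dataset.y[train]).predict(dataset.X[held])
        try:
            e_hat[held] = propensity_learner.build().fit(
                dataset.X[train], dataset.a[train]).predict(dataset.X[held])
        except ValueError:
            e_hat[held] = dataset.a[train].mean()
    return m_hat, clip_probabilities(e_hat, *clip)


def fit_pooled_rlearner(dataset: MultiStudyDataset, m_pooled: np.ndarray,
                        e_pooled: np.ndarray, basis: StudyBasis,
                        lam: float = 0.0, P: np.ndarray | None = None) -> PooledFit:
    """Standard R-learner on the pooled data with supplied pooled nuisances."""
    V = basis.evaluate(dataset.X)
    U = V * (dataset.a - e_pooled)[:, None]
    y_t = dataset.y - m_pooled
    beta = _solve_penalized(U, y_t, lam, P)
    return PooledFit(beta=beta, basis=basis, lam=lam,
                     in_sample_loss=float(np.mean((y_t - U @ beta) ** 2)))


def predict_pooled(fit: PooledFit, Xnew: np.ndarray) -> np.ndarray:
    return fit.basis.evaluate(np.atleast_2d(Xnew)) @ fit.beta
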
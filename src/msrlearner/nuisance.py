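"""Cross-fitted nuisance estimation: study means, propensities, membership, pooled mean.

The three-step procedure needs, for every pooled sample i and every study k:

- m_k(X_i) = E[Y | X_i, S=k], the study-specific conditional mean outcome;
- e_k(X_i) = pr(A=1 | X_i, S=k), the study-specific propensity;
- p(k | X_i) = pr(S=k | X_i), the membership probability;
- the composed pooled mean m(X_i) = sum_k m_k(X_i) p(k | X_i).

Cross-fitting rule: for sample i inside study k, the prediction excludes sample i's
within-study fold q_k(i); for sample i outside study k, the model fit on all of study k
is used (i never enters that training set). Membership probabilities are cross-fitted
on pooled, study-stratified folds q(i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .basis import MembershipBasis
from .data import FoldAssignment, MultiStudyDataset
from .learners import Learner, LearnerSpec

PROPENSITY_CLIP = (0.01, 0.99)
MEMBERSHIP_CLIP = (0.001, 0.999)


def clip_probabilities(values: np.ndarray, lower: float, upper: float,
                       renormalize_rows: bool = False) -> np.ndarray:
    """Elementwise clamp to [lower, upper]; optionally renormalize rows to sum 1."""
    if not (0.0 < lower < upper < 1.0):
        raise ValueError("need 0 < lower < upper < 1")
    out = np.clip(np.asarray(values, dtype=float), lower, upper)
    if renormalize_rows:
        out = out / out.sum(axis=1, keepdims=True)
    return out


@dataclass
class MembershipModel:
    """Semi-parametric multinomial membership model with reference category K.

    p(k | x) = exp(v~(x)' gamma_k) / (1 + sum_{j<K} exp(v~(x)' gamma_j)), with
    gamma_K = 0. ``gamma`` has shape (K-1, d~) on the basis ``v~``.
    """

    gamma: np.ndarray  # (K-1, d_tilde)
    basis: MembershipBasis
    K: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.K == 1:
            return np.ones((X.shape[0], 1))
        return self.proba_from_gamma(self.basis.evaluate(X), self.gamma)

    @staticmethod
    def proba_from_gamma(V: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        """Softmax with an implicit zero row for the reference category."""
        logits = V @ gamma.T  # (n, K-1)
        full = np.hstack([logits, np.zeros((V.shape[0], 1))])
        full -= full.max(axis=1, keepdims=True)
        ex = np.exp(full)
        return ex / ex.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {"gamma": self.gamma.tolist(), "basis": self.basis.to_dict(), "K": self.K}

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipModel":
        return cls(np.asarray(d["gamma"], dtype=float), MembershipBasis.from_dict(d["basis"]),
                   int(d["K"]))


@dataclass
class NuisanceSet:
    """Cross-fitted nuisance predictions plus full-data refits for test-time use."""

    m_k_cross: np.ndarray  # (n, K)
    e_k_cross: np.ndarray  # (n, K), clipped
    p_cross: np.ndarray  # (n, K), clipped + renormalized
    m_pooled: np.ndarray  # (n,)
    m_full: list = field(default_factory=list)  # per-study callables X -> (n,)
    e_full: list = field(default_factory=list)  # per-study callables X -> (n,)
    membership: MembershipModel | None = None
    propensity_clip: tuple = PROPENSITY_CLIP
    membership_clip: tuple = MEMBERSHIP_CLIP
    train_log: list = field(default_factory=list)  # (target, k, train_idx, predict_idx)

    def validate(self) -> None:
        for name, arr in (("m_k_cross", self.m_k_cross), ("e_k_cross", self.e_k_cross),
                          ("p_cross", self.p_cross), ("m_pooled", self.m_pooled)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")
        if np.any(self.e_k_cross <= 0) or np.any(self.e_k_cross >= 1):
            raise ValueError("propensities must lie in (0,1) after clipping")
        if np.max(np.abs(self.p_cross.sum(axis=1) - 1)) > 1e-8:
            raise ValueError("membership rows must sum to 1")


def _mean_fallback(train_y):
    mu = float(np.mean(train_y))
    return lambda X: np.full(np.atleast_2d(X).shape[0], mu)


def fit_study_mean_outcomes(dataset: MultiStudyDataset, folds: FoldAssignment,
                            learner: LearnerSpec):
    """Cross-fitted study-specific conditional mean outcomes.

    Returns (m_cross (n, K), full_predictors list, train_log).
    """
    n, K = dataset.n, dataset.K
    m_cross = np.empty((n, K))
    full_preds, log = [], []
    for k in range(1, K + 1):
        idx = dataset.study_index(k)
        for q in range(1, folds.Q + 1):
            held = idx[folds.within_study_fold[idx] == q]
            train = idx[folds.within_study_fold[idx] != q]
            try:
                model = learner.build().fit(dataset.X[train], dataset.y[train])
            except Exception as exc:  # noqa: BLE001 - annotate with fold/study identity
                raise RuntimeError(f"study {k} fold {q}: mean-outcome learner failed") from exc
            m_cross[held, k - 1] = model.predict(dataset.X[held])
            log.append(("m", k, train, held))
        full = learner.build().fit(dataset.X[idx], dataset.y[idx])
        other = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if other.size:
            m_cross[other, k - 1] = full.predict(dataset.X[other])
        log.append(("m", k, idx, other))
        full_preds.append(full.predict)
    return m_cross, full_preds, log


def fit_study_propensities(dataset: MultiStudyDataset, folds: FoldAssignment,
                           learner: LearnerSpec, known: dict | None = None,
                           clip: tuple = PROPENSITY_CLIP):
    """Cross-fitted study-specific propensities e_k(X_i) for all i, k.

    ``known`` maps study label k -> constant or callable used verbatim (RCT designs);
    estimated studies use a binary-probability learner with the same fold-exclusion
    rule as the mean outcomes. Output clipped to ``clip``.
    """
    known = known or {}
    n, K = dataset.n, dataset.K
    e_cross = np.empty((n, K))
    full_preds, log = [], []
    for k in range(1, K + 1):
        idx = dataset.study_index(k)
        if k in known:
            spec = known[k]
            fn = spec if callable(spec) else (lambda X, c=float(spec): np.full(np.atleast_2d(X).shape[0], c))
            e_cross[:, k - 1] = fn(dataset.X)
            full_preds.append(fn)
            continue
        arms = dataset.arms_present(k)
        if arms != {0, 1}:
            raise ValueError(
                f"study {dataset.study_labels[k - 1]} has a single treatment arm {arms} and no "
                "known propensity: within-study positivity fails"
            )
        for q in range(1, folds.Q + 1):
            held = idx[folds.within_study_fold[idx] == q]
            train = idx[folds.within_study_fold[idx] != q]
            try:
                model = learner.build().fit(dataset.X[train], dataset.a[train])
                pred = model.predict(dataset.X[held])
            except ValueError:
                # a fold's training split may be single-arm even if the study is not
                pred = np.full(held.size, dataset.a[train].mean())
            e_cross[held, k - 1] = pred
            log.append(("e", k, train, held))
        full = learner.build().fit(dataset.X[idx], dataset.a[idx])
        other = np.setdiff1d(np.arange(n), idx)
        if other.size:
            e_cross[other, k - 1] = full.predict(dataset.X[other])
        log.append(("e", k, idx, other))
        full_preds.append(full.predict)
    return clip_probabilities(e_cross, *clip), full_preds, log


def _gamma_from_sklearn(model: LogisticRegression, K: int, d: int) -> np.ndarray:
    """Reference-category coefficients from sklearn's softmax parameterization.

    Softmax probabilities are invariant to subtracting the reference class's
    coefficient row, so gamma_k = w_k - w_K reproduces sklearn's fit exactly.
    Classes absent from training (never the case with stratified folds) get -inf-like
    large negative intercepts via a zero row, which cannot occur here by construction.
    """
    classes = list(model.classes_)
    W = np.zeros((K, d))
    if len(classes) == 2 and model.coef_.shape[0] == 1:
        # binary: coef_ is for classes_[1]
        W[classes[1] - 1] = model.coef_[0]
    else:
        for row, c in zip(model.coef_, classes):
            W[c - 1] = row
    return W[: K - 1] - W[K - 1]


def fit_membership(dataset: MultiStudyDataset, folds: FoldAssignment,
                   membership_basis: MembershipBasis | None = None,
                   learner: LearnerSpec | None = None,
                   clip: tuple = MEMBERSHIP_CLIP):
    """Cross-fitted membership probabilities and the full-data membership model.

    The full-data model is an unpenalized multinomial logistic fit on the membership
    basis (reference category K); its coefficients gamma feed the sandwich variance.
    Cross-fitted probabilities use per-fold refits on the pooled, study-stratified
    folds. With K=2 this is logistic regression on v~(x).
    """
    n, K = dataset.n, dataset.K
    if K == 1:
        model = MembershipModel(np.zeros((0, 1)), membership_basis
                                or MembershipBasis.linear(dataset.p), 1)
        return model, np.ones((n, 1))
    basis = membership_basis or MembershipBasis.linear(dataset.p)
    V = basis.evaluate(dataset.X)

    def _fit(rows) -> LogisticRegression:
        if len(np.unique(dataset.s[rows])) < K:
            raise ValueError(
                "a membership training split is missing a study entirely; "
                "use study-stratified pooled folds"
            )
        lr = LogisticRegression(C=np.inf, fit_intercept=False, max_iter=500, tol=1e-8)
        lr.fit(V[rows], dataset.s[rows])
        return lr

    p_cross = np.empty((n, K))
    for q in range(1, folds.Q + 1):
        held = np.flatnonzero(folds.pooled_fold == q)
        train = np.flatnonzero(folds.pooled_fold != q)
        gamma_q = _gamma_from_sklearn(_fit(train), K, basis.dim)
        p_cross[held] = MembershipModel.proba_from_gamma(V[held], gamma_q)
    gamma = _gamma_from_sklearn(_fit(np.arange(n)), K, basis.dim)
    model = MembershipModel(gamma, basis, K)
    return model, clip_probabilities(p_cross, *clip, renormalize_rows=True)


def compose_pooled_mean(m_k_cross: np.ndarray, p_cross: np.ndarray) -> np.ndarray:
    """Pooled conditional mean m(X_i) = sum_k m_k(X_i) p(k | X_i), per sample."""
    m_k_cross = np.atleast_2d(m_k_cross)
    p_cross = np.atleast_2d(p_cross)
    if m_k_cross.shape != p_cross.shape:
        raise ValueError("m_k_cross and p_cross must share shape (n, K)")
    return np.einsum("nk,nk->n", m_k_cross, p_cross)


def fit_nuisances(dataset: MultiStudyDataset, folds: FoldAssignment,
                  outcome_learner: LearnerSpec | None = None,
                  propensity_learner: LearnerSpec | None = None,
                  membership_learner: LearnerSpec | None = None,
                  membership_basis: MembershipBasis | None = None,
                  known_propensities: dict | None = None) -> NuisanceSet:
    """Convenience wrapper running all nuisance fits (Steps 1 and 2)."""
    outcome_learner = outcome_learner or LearnerSpec("regression", "elastic-net", "spline")
    propensity_learner = propensity_learner or LearnerSpec("binary-probability",
                                                           "logistic-cv", "spline")
    m_cross, m_full, log_m = fit_study_mean_outcomes(dataset, folds, outcome_learner)
    e_cross, e_full, log_e = fit_study_propensities(dataset, folds, propensity_learner,
                                                    known=known_propensities)
    membership, p_cross = fit_membership(dataset, folds, membership_basis, membership_learner)
    ns = NuisanceSet(
        m_k_cross=m_cross,
        e_k_cross=e_cross,
        p_cross=p_cross,
        m_pooled=compose_pooled_mean(m_cross, p_cross),
        m_full=m_full,
        e_full=e_full,
        membership=membership,
        train_log=log_m + log_e,
    )
    ns.validate()
    return ns


def nuisances_from_truth(dataset: MultiStudyDataset, m_k_fn, e_k_fn, p_fn) -> NuisanceSet:
    """Oracle nuisances: plug true functions in (simulation / diagnostic use).

    ``m_k_fn``, ``e_k_fn``, ``p_fn`` map an (n, p) matrix to (n, K) matrices.
    """
    X = dataset.X
    m = np.atleast_2d(np.asarray(m_k_fn(X), dtype=float))
    e = clip_probabilities(np.asarray(e_k_fn(X), dtype=float), *PROPENSITY_CLIP)
    p = clip_probabilities(np.asarray(p_fn(X), dtype=float), *MEMBERSHIP_CLIP,
                           renormalize_rows=True)
    K = dataset.K
    m_full = [lambda Xn, k=k: np.asarray(m_k_fn(np.atleast_2d(Xn)))[:, k] for k in range(K)]
    e_full = [lambda Xn, k=k: np.asarray(e_k_fn(np.atleast_2d(Xn)))[:, k] for k in range(K)]
    ns = NuisanceSet(
        m_k_cross=m,
        e_k_cross=e,
        p_cross=p,
        m_pooled=compose_pooled_mean(m, p),
        m_full=m_full,
        e_full=e_full,
        membership=None,
    )
    ns.validate()
    return ns
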
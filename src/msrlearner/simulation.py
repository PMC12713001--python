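"""Synthetic multi-study generators, train/test splitting, and the replicate harness.

The generators emulate a multi-study design with partially overlapping covariate
supports: each study draws Gaussian covariates with a shared compound-symmetry
covariance and a study-specific mean shift. Because equal-covariance Gaussian study
populations imply an exactly multinomial-logistic membership law, the Scenario A
membership truth p*(k|x) is the analytic LDA posterior of the sampling mechanism —
so p* is the true conditional law of S given X, not merely a modelling choice.

Scenario A: linear study-specific CATEs tau*_k(x) = x'beta + z_k'eta_k with a shared
fixed-effect draw beta ~ MVN(0, I_p) per replicate and random effects
eta_k ~ MVN(0, sigma_tau^2 I_q) on the first q covariates.

Scenario B: non-linear CATEs
tau*_k(x) = sin(2 x1 + 2 eta_k1) + log|x2 + eta_k2| + cos(x3 + eta_k3)(x4 + eta_k4)^2,
with a tree-ensemble membership truth frozen from a large provisional draw.

Baselines are linear with random study intercepts (mu0_k(x) = x'alpha + a_k), errors
are Gaussian, and treatment is assigned per patient from study-specific propensities
(default 0.5 in every study, an RCT-style design under which the multi-study R-loss
moment is exactly centred; heterogeneous propensities are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .basis import BasisSpec, MembershipBasis
from .comparators import fit_study_specific_rlearner, predict_study_specific
from .data import MultiStudyDataset, make_folds
from .estimator import fit_multistudy_rlearner, predict_cate
from .inference import interval_table, stacked_scores, test_zero_ate
from .learners import LearnerSpec
from .nuisance import MembershipModel, fit_nuisances, nuisances_from_truth


@dataclass
class ScenarioConfig:
    """Study conditions for one simulation scenario."""

    scenario: str = "A"
    K: int = 3
    p: int = 10
    q: int | None = None  # random-effect covariates; default min(5, p), Scenario B uses 4
    n_k: tuple = (300, 300, 300)
    sigma_tau: float = 0.5  # between-study CATE heterogeneity SD
    sigma_eps: float = 1.0  # error SD, shared across studies by default
    propensities: tuple | float = 0.5  # per-study constant treatment probabilities
    covariate_shift: float = 1.0  # magnitude of study mean shifts
    rho: float = 0.2  # compound-symmetry correlation
    train_q: float = 0.85
    test_q: float = 0.90
    replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("A", "B"):
            raise ValueError("scenario must be 'A' or 'B'")
        if self.q is None:
            self.q = min(5, self.p)
        if self.scenario == "B":
            self.q = 4
        if self.sigma_tau < 0:
            raise ValueError("sigma_tau must be >= 0")
        if self.q > self.p:
            raise ValueError("q must be <= p")
        if len(self.n_k) != self.K:
            raise ValueError("n_k must have one entry per study")
        if min(self.n_k) < 50:
            raise ValueError("n_k must be >= 50 per study")

    @property
    def e_k(self) -> np.ndarray:
        e = self.propensities
        return np.full(self.K, float(e)) if np.isscalar(e) else np.asarray(e, dtype=float)

    @property
    def sigma_k(self) -> np.ndarray:
        s = self.sigma_eps
        return np.full(self.K, float(s)) if np.isscalar(s) else np.asarray(s, dtype=float)


@dataclass
class Population:
    """Fixed covariate mixture: study means, shared covariance, mixture weights."""

    means: np.ndarray  # (K, p)
    cov: np.ndarray  # (p, p)
    pis: np.ndarray  # (K,)
    chol: np.ndarray
    gamma_star: np.ndarray  # (K-1, p+1), LDA-implied multinomial-logistic truth

    def p_star(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.gamma_star.shape[0] == 0:
            return np.ones((X.shape[0], 1))
        V = np.hstack([np.ones((X.shape[0], 1)), X])
        return MembershipModel.proba_from_gamma(V, self.gamma_star)

    def membership_model(self) -> MembershipModel:
        K = self.means.shape[0]
        return MembershipModel(self.gamma_star, MembershipBasis.linear(self.means.shape[1]), K)


def make_population(config: ScenarioConfig) -> Population:
    """Derive the fixed covariate mixture (and its exact membership law) from the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    K, p = config.K, config.p
    means = np.zeros((K, p))
    for k in range(K):
        direction = rng.standard_normal(p)
        means[k] = config.covariate_shift * direction / np.linalg.norm(direction)
    cov = (1 - config.rho) * np.eye(p) + config.rho * np.ones((p, p))
    pis = np.asarray(config.n_k, dtype=float) / sum(config.n_k)
    cov_inv = np.linalg.inv(cov)
    gamma = np.zeros((K - 1, p + 1))
    muK = means[-1]
    for k in range(K - 1):
        slope = cov_inv @ (means[k] - muK)
        intercept = np.log(pis[k] / pis[-1]) - 0.5 * (means[k] + muK) @ cov_inv @ (means[k] - muK)
        gamma[k, 0] = intercept
        gamma[k, 1:] = slope
    return Population(means=means, cov=cov, pis=pis, chol=np.linalg.cholesky(cov),
                      gamma_star=gamma)


@dataclass
class SimulationTruth:
    """True structural functions for one replicate; all evaluable at arbitrary x."""

    tau_k: callable  # X -> (n, K)
    mu0_k: callable  # X -> (n, K)
    e_k: callable  # X -> (n, K)
    p_star: callable  # X -> (n, K)
    sigma_k: np.ndarray
    population: Population
    params: dict = field(default_factory=dict)

    def tau_bar(self, X: np.ndarray) -> np.ndarray:
        """Target CATE tau*(x) = sum_k tau*_k(x) p*(k|x)."""
        return np.einsum("nk,nk->n", self.tau_k(X), self.p_star(X))

    def m_k(self, X: np.ndarray) -> np.ndarray:
        """Study conditional means m*_k(x) = mu0_k(x) + e_k(x) tau*_k(x)."""
        return self.mu0_k(X) + self.e_k(X) * self.tau_k(X)

    def m_star(self, X: np.ndarray) -> np.ndarray:
        """Pooled conditional mean m*(x) = sum_k m*_k(x) p*(k|x)."""
        return np.einsum("nk,nk->n", self.m_k(X), self.p_star(X))


def _baseline_and_propensity(config: ScenarioConfig, rng: np.random.Generator):
    p, K = config.p, config.K
    alpha = rng.normal(0, 1 / np.sqrt(p), size=p)
    a_k = rng.standard_normal(K)
    e_const = config.e_k

    def mu0_k(X):
        X = np.atleast_2d(X)
        return X @ alpha[:, None] + a_k[None, :]

    def e_k(X):
        return np.tile(e_const, (np.atleast_2d(X).shape[0], 1))

    return mu0_k, e_k, alpha, a_k


def make_truth_scenario_a(config: ScenarioConfig, seed: int, null: bool = False,
                          population: Population | None = None) -> SimulationTruth:
    """Linear CATEs with a shared fixed effect and per-study random effects.

    ``null=True`` forces tau*_k == 0 (type-I-error companion runs).
    """
    pop = population or make_population(config)
    rng = np.random.default_rng(seed)
    p, q, K = config.p, config.q, config.K
    beta = np.zeros(p) if null else rng.standard_normal(p)
    eta = np.zeros((K, q)) if null else rng.normal(0, config.sigma_tau, size=(K, q))
    mu0_k, e_k, alpha, a_k = _baseline_and_propensity(config, rng)

    def tau_k(X):
        X = np.atleast_2d(X)
        return (X @ beta)[:, None] + X[:, :q] @ eta.T

    return SimulationTruth(tau_k=tau_k, mu0_k=mu0_k, e_k=e_k, p_star=pop.p_star,
                           sigma_k=config.sigma_k, population=pop,
                           params={"beta": beta, "eta": eta, "alpha": alpha, "a_k": a_k})


def make_truth_scenario_b(config: ScenarioConfig, seed: int, null: bool = False,
                          population: Population | None = None,
                          membership_forest=None) -> SimulationTruth:
    """Non-linear CATEs; membership truth frozen from a tree ensemble.

    The forest is fit to a large provisional draw from the covariate mechanism and its
    probability function frozen as p*(k|.). Pass ``membership_forest`` to reuse one
    frozen truth across replicates.
    """
    pop = population or make_population(config)
    rng = np.random.default_rng(seed)
    K = config.K
    eta = np.zeros((K, 4)) if null else rng.normal(0, config.sigma_tau, size=(K, 4))
    mu0_k, e_k, alpha, a_k = _baseline_and_propensity(config, rng)
    forest = membership_forest or freeze_membership_forest(config, pop)

    def tau_k(X):
        X = np.atleast_2d(X)
        cols = []
        for k in range(K):
            t = (np.sin(2 * X[:, 0] + 2 * eta[k, 0])
                 + np.log(np.maximum(np.abs(X[:, 1] + eta[k, 1]), 1e-6))
                 + np.cos(X[:, 2] + eta[k, 2]) * (X[:, 3] + eta[k, 3]) ** 2)
            cols.append(np.zeros(X.shape[0]) if null else t)
        return np.column_stack(cols)

    def p_star(X):
        proba = forest.predict_proba(np.atleast_2d(X))
        out = np.zeros((proba.shape[0], K))
        for j, c in enumerate(forest.classes_):
            out[:, int(c) - 1] = proba[:, j]
        return np.clip(out, 1e-6, 1.0) / np.clip(out, 1e-6, 1.0).sum(axis=1, keepdims=True)

    return SimulationTruth(tau_k=tau_k, mu0_k=mu0_k, e_k=e_k, p_star=p_star,
                           sigma_k=config.sigma_k, population=pop,
                           params={"eta": eta, "alpha": alpha, "a_k": a_k})


def freeze_membership_forest(config: ScenarioConfig, population: Population,
                             n_provisional: int = 4000) -> RandomForestClassifier:
    """Fit and freeze the tree-ensemble membership truth on a provisional draw."""
    scaled = replace(config, n_k=tuple(
        max(50, int(round(n_provisional * pi))) for pi in population.pis))
    X, S = sample_covariates(scaled, seed=config.seed + 7919, population=population)
    forest = RandomForestClassifier(n_estimators=100, min_samples_leaf=25,
                                    random_state=config.seed)
    forest.fit(X, S)
    return forest


def make_truth(config: ScenarioConfig, seed: int, null: bool = False,
               population: Population | None = None, **kw) -> SimulationTruth:
    if config.scenario == "A":
        return make_truth_scenario_a(config, seed, null=null, population=population)
    return make_truth_scenario_b(config, seed, null=null, population=population, **kw)


def sample_covariates(config: ScenarioConfig, seed: int,
                      population: Population | None = None):
    """Draw per-study covariates (exact sizes n_k) from the Gaussian mixture.

    Returns (X, S) with S in 1..K, rows grouped by study.
    """
    pop = population or make_population(config)
    rng = np.random.default_rng(seed)
    Xs, Ss = [], []
    for k in range(config.K):
        Z = rng.standard_normal((config.n_k[k], config.p))
        Xs.append(Z @ pop.chol.T + pop.means[k])
        Ss.append(np.full(config.n_k[k], k + 1))
    return np.vstack(Xs), np.concatenate(Ss).astype(int)


def generate_outcomes(truth: SimulationTruth, X: np.ndarray, S: np.ndarray, seed: int):
    """Assign treatment per patient and generate outcomes with Gaussian errors.

    Returns (A, Y, Y0, Y1); potential outcomes are retained for metric computation.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    rows = np.arange(n)
    e = truth.e_k(X)[rows, S - 1]
    A = (rng.random(n) < e).astype(int)
    eps = rng.standard_normal(n) * truth.sigma_k[S - 1]
    Y0 = truth.mu0_k(X)[rows, S - 1] + eps
    Y1 = Y0 + truth.tau_k(X)[rows, S - 1]
    Y = np.where(A == 1, Y1, Y0)
    return A, Y, Y0, Y1


def mahalanobis_split(X: np.ndarray, train_q: float = 0.85, test_q: float = 0.90):
    """Split rows by Mahalanobis distance from the pooled centroid.

    Distances below the ``train_q`` quantile go to the training set, above the
    ``test_q`` quantile to the test set; the band between is discarded so the two
    covariate regions do not overlap.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 5 * p:
        raise ValueError(f"n={n} too small for a stable covariance at p={p} (need n >= 5p)")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.inv(cov + 1e-6 * np.eye(p))
    Z = X - mu
    d = np.einsum("ij,jk,ik->i", Z, cov_inv, Z)
    lo, hi = np.quantile(d, [train_q, test_q])
    train = np.flatnonzero(d < lo)
    test = np.flatnonzero(d >= hi)
    discard = np.setdiff1d(np.arange(n), np.union1d(train, test))
    return train, test, discard


# -- replicate harness ----------------------------------------------------

_LEARNER_SETS = {
    "elastic-net": dict(
        outcome=LearnerSpec("regression", "elastic-net", "spline"),
        propensity=LearnerSpec("binary-probability", "logistic-cv", "spline"),
    ),
    "ols": dict(
        outcome=LearnerSpec("regression", "ols", "none"),
        propensity=LearnerSpec("binary-probability", "logistic", "none"),
    ),
}


def run_single_replicate(config: ScenarioConfig, truth: SimulationTruth, seed: int,
                         methods=("multi-study",), nuisance_mode: str = "elastic-net",
                         lam: float = 0.0, nominal: float = 0.95, Q: int = 5):
    """One end-to-end replicate: draw data, split, fit nuisances and methods, evaluate.

    Returns a dict with per-test-point truths, predictions, and (for the multi-study
    method) standard errors, interval coverage flags, and the zero-ATE test p-value.
    """
    sub = np.random.SeedSequence(seed).generate_state(4)
    X, S = sample_covariates(config, int(sub[0]), population=truth.population)
    A, Y, _, _ = generate_outcomes(truth, X, S, int(sub[1]))
    train, test, _ = mahalanobis_split(X, config.train_q, config.test_q)
    ds = MultiStudyDataset(y=Y[train], a=A[train], s=S[train], X=X[train])
    folds = make_folds(ds, Q=Q, seed=int(sub[2]) % (2**31 - 1))

    if nuisance_mode == "oracle":
        ns = nuisances_from_truth(ds, truth.m_k, truth.e_k, truth.p_star)
        ns.membership = truth.population.membership_model()
    else:
        learners = _LEARNER_SETS[nuisance_mode]
        ns = fit_nuisances(ds, folds, outcome_learner=learners["outcome"],
                           propensity_learner=learners["propensity"],
                           membership_basis=MembershipBasis.linear(config.p))

    if config.scenario == "A":
        basis = BasisSpec.linear(ds.K, ds.p)
    else:
        basis = BasisSpec.spline_from_data(ds.K, ds.X, n_knots=5)

    X_test = X[test]
    tau_star = truth.tau_bar(X_test)
    out = {"tau_star": tau_star, "X_test": X_test, "n_train": ds.n}

    if "multi-study" in methods:
        fit = fit_multistudy_rlearner(ds, ns, basis, lam=lam)
        scores = stacked_scores(fit, ds, ns)
        tau_hat, se, lower, upper = interval_table(fit, scores, X_test, level=nominal)
        z, pval = test_zero_ate(fit, scores, X_test)
        out["multi-study"] = {
            "tau_hat": tau_hat, "se": se,
            "covered": (lower <= tau_star) & (tau_star <= upper),
            "zero_ate_p": pval, "fit": fit, "scores": scores,
        }
    if "study-specific" in methods:
        ss = fit_study_specific_rlearner(ds, ns, basis, lam=lam)
        out["study-specific"] = {
            "tau_hat": predict_study_specific(ss, X_test, membership=ns.membership)
            if ns.membership is not None else predict_study_specific(ss, X_test),
            "fit": ss,
        }
    return out


@dataclass
class MetricsTable:
    """Per-method simulation metrics with Monte-Carlo standard errors."""

    table: pd.DataFrame
    per_replicate: pd.DataFrame
    config: ScenarioConfig
    n_failures: int = 0


def run_replicates(config: ScenarioConfig, methods=("multi-study", "study-specific"),
                   nominal: float = 0.95, null: bool = False,
                   nuisance_mode: str = "elastic-net", lam: float = 0.0,
                   fix_truth: bool = False, alpha: float = 0.05) -> MetricsTable:
    """Replicate loop computing bias, variance, coverage and type-I error.

    Per replicate: draw truths (once if ``fix_truth``), covariates and outcomes;
    split by Mahalanobis distance; cross-fit nuisances; fit the requested methods on
    the training region and evaluate on the held-out tail region. Coverage and the
    zero-ATE test use the multi-study sandwich intervals. ``null=True`` forces
    tau*_k == 0 so the rejection rate estimates the type-I error.
    """
    R = config.replicates
    master = np.random.SeedSequence(config.seed)
    truth_seeds, rep_seeds = master.spawn(2)
    truth_states = truth_seeds.generate_state(R if not fix_truth else 1)
    rep_states = rep_seeds.generate_state(R)
    pop = make_population(config)
    forest = (freeze_membership_forest(config, pop) if config.scenario == "B" else None)
    kw = {"membership_forest": forest} if config.scenario == "B" else {}

    rows, failures = [], 0
    fixed_truth = (make_truth(config, int(truth_states[0]), null=null, population=pop, **kw)
                   if fix_truth else None)
    for r in range(R):
        truth = fixed_truth or make_truth(config, int(truth_states[r]), null=null,
                                          population=pop, **kw)
        try:
            res = run_single_replicate(config, truth, int(rep_states[r]), methods=methods,
                                       nuisance_mode=nuisance_mode, lam=lam, nominal=nominal)
        except Exception:  # noqa: BLE001 - replicate-level failures are counted
            failures += 1
            if failures > max(1, int(0.05 * R)):
                raise RuntimeError(f">5% of replicates failed ({failures}/{r + 1})")
            continue
        for method in methods:
            m = res[method]
            err = m["tau_hat"] - res["tau_star"]
            row = {"replicate": r, "method": method, "sigma_tau": config.sigma_tau,
                   "bias": float(err.mean()),
                   "mean_tau_hat": float(m["tau_hat"].mean())}
            if method == "multi-study":
                row["coverage"] = float(m["covered"].mean())
                row["reject"] = bool(m["zero_ate_p"] < alpha)
            rows.append(row)
    per_rep = pd.DataFrame(rows)

    out_rows = []
    for method in methods:
        sub = per_rep[per_rep.method == method]
        Reff = len(sub)
        row = {"method": method, "sigma_tau": config.sigma_tau, "replicates": Reff,
               "bias": sub.bias.mean(), "bias_mc_se": sub.bias.std(ddof=1) / np.sqrt(Reff),
               "variance": sub.mean_tau_hat.var(ddof=1)}
        if method == "multi-study":
            cov = sub.coverage.mean()
            row["coverage"] = cov
            row["coverage_mc_se"] = sub.coverage.std(ddof=1) / np.sqrt(Reff)
            rej = sub.reject.mean()
            row["type_1_error" if null else "rejection_rate"] = rej
            row["rejection_mc_se"] = np.sqrt(rej * (1 - rej) / Reff)
        out_rows.append(row)
    return MetricsTable(table=pd.DataFrame(out_rows), per_replicate=per_rep,
                        config=config, n_failures=failures)


def metrics_over_grid(config: ScenarioConfig, sigma_taus, **kw) -> pd.DataFrame:
    """Run the harness across a heterogeneity grid and stack the metric tables."""
    tables = []
    for st in sigma_taus:
        mt = run_replicates(replace(config, sigma_tau=float(st)), **kw)
        tables.append(mt.table)
    return pd.concat(tables, ignore_index=True)


# -- efficiency comparison (two-study heterogeneous-propensity regime) ----

def efficiency_study(n_per_study: int = 1000, replicates: int = 300, c: float = 4.0,
                     sigma: float = 2.0, p: int = 2, seed: int = 0, n_eval: int = 5):
    """Empirical variance of the multi-study vs study-specific estimators.

    Two studies with equal membership p*(k|x) = 1/2, a common linear basis, constant
    propensities e1 = 0.5 and e2 solving e2(1-e2) = e1(1-e1)/c, homogeneous baseline
    and CATE functions (so the R-loss moment is exactly centred), and error SD
    ``sigma``. Oracle nuisances isolate the asymptotic design effect: the pooled fit
    is predicted to win when sigma^2 exceeds (1+c)/(2 sqrt(c)).
    """
    rng = np.random.default_rng(seed)
    e1 = 0.5
    e2 = 0.5 * (1.0 - np.sqrt(max(0.0, 1.0 - e1 * (1 - e1) / c * 4)))
    e_const = np.array([e1, e2])
    beta_true = rng.standard_normal(p + 1)
    alpha_true = rng.standard_normal(p + 1) * 0.5
    X_eval = rng.standard_normal((n_eval, p))
    memb = MembershipModel(np.zeros((1, p + 1)), MembershipBasis.linear(p), 2)

    def with_intercept(X):
        return np.hstack([np.ones((X.shape[0], 1)), X])

    tau_ms = np.empty((replicates, n_eval))
    tau_ss = np.empty((replicates, n_eval))
    basis = BasisSpec.linear(2, p)
    for r in range(replicates):
        n = 2 * n_per_study
        X = rng.standard_normal((n, p))
        S = np.repeat([1, 2], n_per_study)
        e = e_const[S - 1]
        A = (rng.random(n) < e).astype(int)
        tau = with_intercept(X) @ beta_true
        mu0 = with_intercept(X) @ alpha_true
        Y = mu0 + A * tau + rng.normal(0, sigma, n)
        ds = MultiStudyDataset(y=Y, a=A, s=S, X=X)
        ns = nuisances_from_truth(
            ds,
            m_k_fn=lambda Xq: np.column_stack([with_intercept(np.atleast_2d(Xq)) @ alpha_true
                                               + ek * (with_intercept(np.atleast_2d(Xq)) @ beta_true)
                                               for ek in e_const]),
            e_k_fn=lambda Xq: np.tile(e_const, (np.atleast_2d(Xq).shape[0], 1)),
            p_fn=lambda Xq: np.full((np.atleast_2d(Xq).shape[0], 2), 0.5),
        )
        ns.membership = memb
        fit = fit_multistudy_rlearner(ds, ns, basis, lam=0.0)
        tau_ms[r] = predict_cate(fit, X_eval)
        ss = fit_study_specific_rlearner(ds, ns, basis, lam=0.0)
        tau_ss[r] = predict_study_specific(ss, X_eval, membership=memb)
    var_ms = tau_ms.var(axis=0, ddof=1).mean()
    var_ss = tau_ss.var(axis=0, ddof=1).mean()
    return {"var_multi_study": float(var_ms), "var_study_specific": float(var_ss),
            "ratio": float(var_ms / var_ss), "threshold": (1 + c) / (2 * np.sqrt(c)),
            "sigma2": sigma**2, "e2": float(e2)}
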
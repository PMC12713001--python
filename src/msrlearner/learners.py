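"""Pluggable nuisance learners behind a small declarative contract.

A :class:`LearnerSpec` names the prediction task (``regression``,
``binary-probability``, ``multiclass-probability``), the model family, and an
optional cubic-spline feature expansion of the covariates. ``build`` turns the
spec into a fitted-interface object with ``fit(X, y)`` and ``predict(X)`` —
probabilities for the probability kinds, conditional means for regression.

The default stack matches common practice for cross-fitted nuisance estimation:
elastic net with cubic-spline expanded covariates and an internally
cross-validated penalty for conditional means, and (multinomial) logistic
regression for probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import (ElasticNetCV, LinearRegression, LogisticRegression,
                                  LogisticRegressionCV)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

KINDS = ("regression", "binary-probability", "multiclass-probability")


@dataclass
class LearnerSpec:
    """Declarative learner description.

    Parameters
    ----------
    kind : one of ``regression``, ``binary-probability``, ``multiclass-probability``.
    model : ``elastic-net`` | ``ols`` | ``mean`` for regression;
        ``logistic`` | ``mean`` for the probability kinds.
    expansion : ``spline`` applies a cubic B-spline expansion with 3 interior
        knots at covariate quantiles (linear extrapolation beyond the boundary);
        ``none`` uses raw covariates.
    seed : seed forwarded to any stochastic fitting internals.
    """

    kind: str = "regression"
    model: str = "elastic-net"
    expansion: str = "spline"
    n_knots: int = 5  # 3 interior + 2 boundary knots
    degree: int = 3
    cv: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")

    def build(self) -> "Learner":
        return Learner(self)


def _expansion_steps(spec: LearnerSpec):
    steps = []
    if spec.expansion == "spline":
        steps.append((
            "spline",
            SplineTransformer(
                n_knots=spec.n_knots,
                degree=spec.degree,
                knots="quantile",
                extrapolation="linear",
                include_bias=False,
            ),
        ))
    elif spec.expansion != "none":
        raise ValueError(f"unknown expansion {spec.expansion!r}")
    steps.append(("scale", StandardScaler()))
    return steps


class Learner:
    """Fitted-interface wrapper: ``fit(X, y)`` then ``predict(X)``.

    ``predict`` returns conditional means for regression, P(y=1) for
    binary-probability, and an (n, n_classes) simplex matrix for
    multiclass-probability (class order = sorted unique labels seen in fit).
    """

    def __init__(self, spec: LearnerSpec):
        self.spec = spec
        self.classes_: np.ndarray | None = None
        self._mean: float | np.ndarray | None = None
        self._est = None

    def _make_estimator(self):
        spec = self.spec
        if spec.kind == "regression":
            if spec.model == "elastic-net":
                core = ElasticNetCV(
                    l1_ratio=0.5,
                    alphas=10,
                    cv=spec.cv,
                    max_iter=2000,
                    tol=1e-3,
                    random_state=spec.seed,
                )
            elif spec.model == "ols":
                core = LinearRegression()
            else:
                raise ValueError(f"unknown regression model {spec.model!r}")
        else:
            if spec.model in ("logistic-cv", "elastic-net"):
                # penalty strength chosen by internal cross-validation, mirroring
                # a cv.glmnet-style fit; essential when the expanded feature set is
                # much richer than the true signal
                core = LogisticRegressionCV(Cs=[0.01, 0.1, 1.0], cv=spec.cv,
                                            scoring="neg_log_loss", max_iter=500)
            elif spec.model == "logistic":
                core = LogisticRegression(C=1.0, max_iter=500)
            else:
                raise ValueError(f"unknown probability model {spec.model!r}")
        return Pipeline(_expansion_steps(spec) + [("model", core)])

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if self.spec.model == "mean":
            if self.spec.kind == "regression":
                self._mean = float(np.mean(y))
            else:
                self.classes_ = np.unique(y)
                self._mean = np.array([np.mean(y == c) for c in self.classes_])
            return self
        if self.spec.kind != "regression":
            self.classes_ = np.unique(y)
            if self.classes_.size < 2:
                raise ValueError(
                    "probability learner needs >= 2 classes in training data "
                    f"(saw {self.classes_.tolist()})"
                )
        self._est = self._make_estimator()
        with warnings.catch_warnings():
            # coordinate descent at loose tolerance may report residual duality gaps;
            # sklearn also warns about upcoming LogisticRegressionCV API transitions
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            self._est.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        kind = self.spec.kind
        if self.spec.model == "mean":
            if kind == "regression":
                return np.full(X.shape[0], self._mean)
            probs = np.tile(self._mean, (X.shape[0], 1))
            return probs[:, 1] if kind == "binary-probability" else probs
        if kind == "regression":
            out = self._est.predict(X)
        elif kind == "binary-probability":
            proba = self._est.predict_proba(X)
            out = proba[:, list(self._est.classes_).index(1)]
        else:
            out = self._est.predict_proba(X)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("learner produced non-finite predictions")
        return out
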
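"""Series (basis-function) expansions for study-specific CATEs and the membership model.

Each study k gets a basis v_k(x) of dimension d_k; the stacked basis
v(x) = (v_1(x), ..., v_K(x)) has dimension d = sum_k d_k. Supported families:

- ``intercept``: v_k(x) = (1,)
- ``linear``: v_k(x) = (1, x_1, ..., x_p)
- ``poly``: per-coordinate powers (1, x_1, ..., x_p, x_1^2, ..., x_p^g), no interactions
- ``spline``: intercept + per-coordinate cubic B-splines with stored knots,
  linear extrapolation beyond the boundary knots.

Bases may differ across studies except in the reparameterized (tau + delta_k) fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import SplineTransformer

FAMILIES = ("intercept", "linear", "poly", "spline")


@dataclass
class StudyBasis:
    """Basis family for one study. ``knots`` is a (n_knots, p) array for splines."""

    family: str
    p: int
    degree: int = 1
    knots: np.ndarray | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.knots is not None:
            self.knots = np.asarray(self.knots, dtype=float)

    @property
    def dim(self) -> int:
        if self.family == "intercept":
            return 1
        if self.family == "linear":
            return 1 + self.p
        if self.family == "poly":
            return 1 + self.p * self.degree
        n_splines = self.knots.shape[0] + 3 - 1 - 1  # cubic, drop one for intercept
        return 1 + self.p * n_splines

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} covariates, got {X.shape[1]}")
        n = X.shape[0]
        ones = np.ones((n, 1))
        if self.family == "intercept":
            return ones
        if self.family == "linear":
            return np.hstack([ones, X])
        if self.family == "poly":
            cols = [ones] + [X**g for g in range(1, self.degree + 1)]
            return np.hstack(cols)
        lo, hi = self.knots[0], self.knots[-1]
        if np.any(X < lo) or np.any(X > hi):
            warnings.warn("basis evaluated beyond spline boundary knots; extrapolating linearly")
        st = SplineTransformer(
            knots=self.knots, degree=3, extrapolation="linear", include_bias=False
        )
        st.fit(np.zeros((2, self.p)))  # knots are supplied; fit only sets bookkeeping
        return np.hstack([ones, st.transform(X)])

    def to_dict(self) -> dict:
        d = {"family": self.family, "p": self.p, "degree": self.degree}
        if self.knots is not None:
            d["knots"] = self.knots.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyBasis":
        knots = np.asarray(d["knots"]) if d.get("knots") is not None else None
        return cls(family=d["family"], p=d["p"], degree=d.get("degree", 1), knots=knots)


@dataclass
class BasisSpec:
    """Per-study basis families; evaluation returns the list [v_1(X), ..., v_K(X)]."""

    studies: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def dims(self) -> list:
        return [b.dim for b in self.studies]

    @property
    def dim(self) -> int:
        return int(sum(self.dims))

    @property
    def block_slices(self) -> list:
        out, start = [], 0
        for d in self.dims:
            out.append(slice(start, start + d))
            start += d
        return out

    def common(self) -> bool:
        first = self.studies[0].to_dict()
        return all(b.to_dict() == first for b in self.studies[1:])

    # -- constructors ------------------------------------------------------
    @classmethod
    def intercept(cls, K: int, p: int) -> "BasisSpec":
        return cls([StudyBasis("intercept", p) for _ in range(K)])

    @classmethod
    def linear(cls, K: int, p: int) -> "BasisSpec":
        return cls([StudyBasis("linear", p) for _ in range(K)])

    @classmethod
    def poly(cls, K: int, p: int, degree: int) -> "BasisSpec":
        return cls([StudyBasis("poly", p, degree=degree) for _ in range(K)])

    @classmethod
    def spline_from_data(cls, K: int, X: np.ndarray, n_knots: int = 5) -> "BasisSpec":
        """Cubic splines with knots at pooled covariate quantiles (shared across studies)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        qs = np.linspace(0, 1, n_knots)
        knots = np.quantile(X, qs, axis=0)
        # guard against ties producing non-increasing knots
        for j in range(knots.shape[1]):
            for i in range(1, knots.shape[0]):
                if knots[i, j] <= knots[i - 1, j]:
                    knots[i, j] = knots[i - 1, j] + 1e-8
        return cls([StudyBasis("spline", X.shape[1], degree=3, knots=knots) for _ in range(K)])

    def evaluate(self, X: np.ndarray) -> list:
        return [b.evaluate(X) for b in self.studies]

    def to_dict(self) -> dict:
        return {"studies": [b.to_dict() for b in self.studies]}

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls([StudyBasis.from_dict(b) for b in d["studies"]])


def evaluate_basis(basis: BasisSpec, X: np.ndarray) -> list:
    """Per-study basis matrices [v_k(X)] of shapes (rows, d_k), intercept column first."""
    return basis.evaluate(X)


@dataclass
class MembershipBasis:
    """Pre-specified basis for the multinomial membership model (shared across studies).

    ``linear`` (default) is an intercept plus raw covariates; ``spline`` shares the
    machinery of :class:`StudyBasis`.
    """

    inner: StudyBasis

    @classmethod
    def linear(cls, p: int) -> "MembershipBasis":
        return cls(StudyBasis("linear", p))

    @classmethod
    def spline_from_data(cls, X: np.ndarray, n_knots: int = 5) -> "MembershipBasis":
        return cls(BasisSpec.spline_from_data(1, X, n_knots).studies[0])

    @property
    def dim(self) -> int:
        return self.inner.dim

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        return self.inner.evaluate(X)

    def to_dict(self) -> dict:
        return self.inner.to_dict()

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipBasis":
        return cls(StudyBasis.from_dict(d))
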
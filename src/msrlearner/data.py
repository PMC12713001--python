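"""Multi-study dataset container, validation, cross-fitting folds, and delimited-text I/O.

A multi-study dataset pools rows ``(y, a, s, x1..xp)`` from K studies: outcome ``y``,
binary treatment ``a``, study label ``s`` (mapped to 1..K in first-appearance order),
and covariates ``X``. Cross-fitting uses two fold systems: pooled folds ``q(i)``
(stratified by study) for quantities estimated on the pooled sample, and within-study
folds ``q_k(i)`` for study-specific nuisances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass
class MultiStudyDataset:
    """Pooled observations from K studies.

    Attributes
    ----------
    y : (n,) float array of outcomes.
    a : (n,) int array of treatment indicators in {0, 1}.
    s : (n,) int array of study labels in {1..K}.
    X : (n, p) float covariate matrix.
    study_labels : original study labels, position k-1 holds the label mapped to k.
    """

    y: np.ndarray
    a: np.ndarray
    s: np.ndarray
    X: np.ndarray
    study_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.a = np.asarray(self.a)
        self.s = np.asarray(self.s, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not self.study_labels:
            self.study_labels = [int(k) for k in range(1, self.K + 1)]
        self.validate()

    # -- shape properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return int(self.s.max()) if self.s.size else 0

    @property
    def n_k(self) -> np.ndarray:
        return np.bincount(self.s, minlength=self.K + 1)[1:]

    def study_index(self, k: int) -> np.ndarray:
        """Row indices of study k (1-based label)."""
        return np.flatnonzero(self.s == k)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        n = self.n
        if not (self.a.shape[0] == n and self.s.shape[0] == n and self.X.shape[0] == n):
            raise ValueError("y, a, s, X must have the same number of rows")
        for name, arr in (("y", self.y), ("X", self.X)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        bad = ~np.isin(self.a, (0, 1))
        if bad.any():
            rows = np.flatnonzero(bad)[:5].tolist()
            raise ValueError(f"treatment must be 0/1; offending rows {rows}")
        self.a = self.a.astype(int)
        K = self.K
        if K < 1 or self.s.min() < 1:
            raise ValueError("study labels must cover 1..K")
        counts = self.n_k
        if (counts < 2).any():
            raise ValueError(f"every study needs >= 2 samples; counts {counts.tolist()}")

    def arms_present(self, k: int) -> set:
        return set(np.unique(self.a[self.s == k]).tolist())


@dataclass
class FoldAssignment:
    """Pooled and within-study fold memberships for Q-fold cross-fitting."""

    Q: int
    pooled_fold: np.ndarray  # q(i) in {1..Q}
    within_study_fold: np.ndarray  # q_k(i) in {1..Q}, defined within sample i's own study
    seed: int


def make_folds(dataset: MultiStudyDataset, Q: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign pooled (study-stratified) and within-study folds.

    Pooled folds partition {1..n} with sizes differing by at most one and per-fold
    study composition matching the pooled proportions to within one sample. Within
    each study, folds partition that study's rows with sizes differing by at most one.
    """
    if Q < 2:
        raise ValueError("Q must be >= 2")
    small = np.flatnonzero(dataset.n_k < Q)
    if small.size:
        labels = [dataset.study_labels[k] for k in small]
        raise ValueError(
            f"studies {labels} have fewer than Q={Q} samples; reduce Q or merge studies"
        )
    n = dataset.n
    pooled = np.empty(n, dtype=int)
    skf = StratifiedKFold(n_splits=Q, shuffle=True, random_state=seed)
    for q, (_, test_idx) in enumerate(skf.split(np.zeros(n), dataset.s), start=1):
        pooled[test_idx] = q
    within = np.empty(n, dtype=int)
    for k in range(1, dataset.K + 1):
        idx = dataset.study_index(k)
        kf = KFold(n_splits=Q, shuffle=True, random_state=seed + k)
        for q, (_, test_pos) in enumerate(kf.split(idx), start=1):
            within[idx[test_pos]] = q
    return FoldAssignment(Q=Q, pooled_fold=pooled, within_study_fold=within, seed=seed)


# -- delimited-text I/O ---------------------------------------------------

DEFAULT_COLUMNS = {"y": "y", "a": "a", "study": "study"}


def read_dataset(path, column_map: dict | None = None, covariate_columns=None) -> MultiStudyDataset:
    """Read a CSV/TSV file with header into a validated :class:`MultiStudyDataset`.

    Study labels are mapped to 1..K in first-appearance order; the mapping is kept in
    ``study_labels``. Rows with missing values are rejected with their row numbers.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for role in ("y", "a", "study"):
        if cols[role] not in df.columns:
            raise ValueError(f"missing required column '{cols[role]}' (role {role})")
    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c not in cols.values()]
    missing = [c for c in covariate_columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariate columns {missing}")
    sub = df[[cols["y"], cols["a"], *covariate_columns]]
    na_rows = sub.isna().any(axis=1) | df[cols["study"]].isna()
    if na_rows.any():
        raise ValueError(f"missing values in rows {np.flatnonzero(na_rows.values).tolist()}")
    a = pd.to_numeric(df[cols["a"]], errors="raise").to_numpy()
    bad = ~np.isin(a, (0, 1))
    if bad.any():
        raise ValueError(
            f"treatment column '{cols['a']}' must be 0/1; offending rows "
            f"{np.flatnonzero(bad).tolist()}"
        )
    raw_s = df[cols["study"]].tolist()
    labels: list = []
    s = np.empty(len(raw_s), dtype=int)
    for i, lab in enumerate(raw_s):
        if lab not in labels:
            labels.append(lab)
        s[i] = labels.index(lab) + 1
    return MultiStudyDataset(
        y=df[cols["y"]].to_numpy(float),
        a=a.astype(int),
        s=s,
        X=df[covariate_columns].to_numpy(float),
        study_labels=labels,
    )


def write_dataset(dataset: MultiStudyDataset, path, column_map: dict | None = None) -> None:
    """Write a dataset back to delimited text (inverse of :func:`read_dataset`)."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.DataFrame({
        cols["y"]: dataset.y,
        cols["a"]: dataset.a,
        cols["study"]: [dataset.study_labels[k - 1] for k in dataset.s],
    })
    for j in range(dataset.p):
        df[f"x{j + 1}"] = dataset.X[:, j]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    # %.17g guarantees bit-exact float round trips through text
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
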
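"""Confound-matched case/control construction.

Cases are paired to controls by solving the rectangular linear assignment
problem on the matrix of Mahalanobis distances between confounder vectors
(age, sex, ethnicity, Townsend deprivation index by default), then pruning
pairs whose distance exceeds a threshold (0.3 by default).  The metric is
defined by the covariance of the pooled case+control confounder matrix
(n−1 normalization), ridge-regularized to be invertible; categorical
confounders are one-hot encoded.  An age-shifted variant matches each case
to controls a fixed number of years younger, which is how an
age-classification dataset (e.g. 70-year-olds vs 60-year-olds) is built.

Matched pairs move through train/validation/test splits *in tandem*: both
members of a pair always land in the same split.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

DEFAULT_CONFOUNDERS = ("age", "sex", "ethnicity", "tdi")
DEFAULT_CATEGORICAL = ("ethnicity",)
DEFAULT_THRESHOLD = 0.3


def confounder_matrix(subjects: pd.DataFrame,
                      confounders=DEFAULT_CONFOUNDERS,
                      categorical=DEFAULT_CATEGORICAL):
    """Encode confounders and estimate their pooled covariance.

    Categorical columns are expanded to full one-hot indicators; the
    covariance uses the n−1 convention and is ridge-regularized so it is
    always invertible (one-hot blocks are rank-deficient by construction;
    difference vectors between subjects are orthogonal to the null
    directions, so the regularization does not distort pair distances).

    Returns ``(X, cov, columns)``.
    """
    for name in confounders:
        if name not in subjects.columns:
            raise KeyError(f"unknown confounder {name!r}")
    blocks, columns = [], []
    for name in confounders:
        col = subjects[name]
        if name in categorical or col.dtype == object:
            onehot = pd.get_dummies(col.astype("category"), prefix=name)
            blocks.append(onehot.to_numpy(dtype=float))
            columns.extend(onehot.columns)
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
            columns.append(name)
    X = np.hstack(blocks)
    if X.shape[0] < 2:
        cov = np.eye(X.shape[1])
    else:
        cov = np.cov(X.T, ddof=1)
        cov = np.atleast_2d(cov)
    diag = np.diag(cov)
    if np.any(diag == 0.0):
        warnings.warn("constant confounder column; ridge-regularizing",
                      stacklevel=2)
    ridge = 1e-8 * max(float(diag.mean()), 1.0)
    cov_reg = cov + ridge * np.eye(cov.shape[0])
    # escalate until the Cholesky factorization succeeds
    while True:
        try:
            np.linalg.cholesky(cov_reg)
            break
        except np.linalg.LinAlgError:
            ridge *= 10.0
            cov_reg = cov + ridge * np.eye(cov.shape[0])
    return X, cov_reg, columns


def mahalanobis(x: np.ndarray, y: np.ndarray, cov_inv: np.ndarray) -> float:
    """sqrt((x−y)ᵀ Σ⁻¹ (x−y)); symmetric, zero iff x = y for PD Σ⁻¹."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or cov_inv.shape != (x.size, x.size):
        raise ValueError("dimension mismatch")
    d = x - y
    return float(np.sqrt(max(d @ cov_inv @ d, 0.0)))


def _distance_matrix(cases: pd.DataFrame, controls: pd.DataFrame,
                     confounders, categorical, age_shift: float):
    """Case × control Mahalanobis distances under the pooled metric.

    ``age_shift`` years are subtracted from each case's age before the
    pooled covariance and the difference vectors are formed, so matching
    with a shift pairs cases to younger controls.
    """
    cases = cases.copy()
    if age_shift:
        cases["age"] = cases["age"] - age_shift
    pooled = pd.concat([cases, controls], ignore_index=True)
    X, cov, _ = confounder_matrix(pooled, confounders, categorical)
    cov_inv = np.linalg.inv(cov)
    Xc, Xk = X[:len(cases)], X[len(cases):]
    return cdist(Xc, Xk, metric="mahalanobis", VI=cov_inv)


def match_cohorts(cases: pd.DataFrame, controls: pd.DataFrame,
                  confounders=DEFAULT_CONFOUNDERS,
                  threshold: float = DEFAULT_THRESHOLD,
                  age_shift: float = 0.0,
                  categorical=DEFAULT_CATEGORICAL) -> pd.DataFrame:
    """Optimal-pair matching with threshold pruning.

    Solves the rectangular assignment problem minimizing the total
    Mahalanobis distance between cases and controls (exact
    Jonker–Volgenant-class solver), then drops pairs with distance above
    ``threshold`` — the threshold is applied *after* the globally optimal
    assignment, not during it.

    Returns a matched set: DataFrame(case_id, control_id, distance).
    """
    if len(cases) == 0 or len(controls) == 0:
        return pd.DataFrame(columns=["case_id", "control_id", "distance"])
    D = _distance_matrix(cases, controls, confounders, categorical, age_shift)
    rows, cols = linear_sum_assignment(D)
    dist = D[rows, cols]
    out = pd.DataFrame({
        "case_id": cases["id"].to_numpy()[rows],
        "control_id": controls["id"].to_numpy()[cols],
        "distance": dist,
    })
    out = out[out["distance"] <= threshold].reset_index(drop=True)
    return out


def split_tandem(matched: pd.DataFrame,
                 fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
                 seed: int = 0) -> pd.DataFrame:
    """Assign whole pairs to train/validation/test splits.

    ``fractions`` is (train, validation, test) and must sum to 1.  Sizes
    are ``round(f_test·n)`` for test, then ``round(f_val·n)`` for
    validation, remainder train; ties are broken by the seeded shuffle
    order.  Both members of a pair share one split by construction.

    Returns the matched set with a ``split`` column added.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if min(fractions) < 0:
        raise ValueError("split fractions must be non-negative")
    n = len(matched)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(f_test * n))
    n_val = int(round(f_val * n))
    if n_test + n_val > n:
        raise ValueError("rounded split sizes exceed the number of pairs")
    split = np.empty(n, dtype=object)
    split[order[:n_test]] = "test"
    split[order[n_test:n_test + n_val]] = "validation"
    split[order[n_test + n_val:]] = "train"
    out = matched.reset_index(drop=True).copy()
    out["split"] = split
    return out


def subject_splits(matched_with_split: pd.DataFrame) -> pd.DataFrame:
    """Flatten a tandem split to one row per subject: (subject_id, split)."""
    parts = []
    for col in ("case_id", "control_id"):
        parts.append(matched_with_split[[col, "split"]]
                     .rename(columns={col: "subject_id"}))
    return pd.concat(parts, ignore_index=True)


def build_generalization_dataset(pool: pd.DataFrame, used_ids,
                                 selector,
                                 age_shift: float = 0.0,
                                 threshold: float = DEFAULT_THRESHOLD,
                                 confounders=DEFAULT_CONFOUNDERS,
                                 categorical=DEFAULT_CATEGORICAL) -> pd.DataFrame:
    """Matched dataset for a generalization test, avoiding reused controls.

    Subjects in ``used_ids`` are removed from the pool; ``selector`` (a
    callable DataFrame → boolean mask) picks the target group (e.g. a
    second disease, or an exact age); the remaining subjects form the
    control pool.  Matching then proceeds as in :func:`match_cohorts`.
    """
    used = set(used_ids)
    avail = pool[~pool["id"].isin(used)].reset_index(drop=True)
    mask = np.asarray(selector(avail), dtype=bool)
    targets = avail[mask].reset_index(drop=True)
    rest = avail[~mask].reset_index(drop=True)
    if len(targets) == 0:
        warnings.warn("selector produced an empty target group", stacklevel=2)
        return pd.DataFrame(columns=["case_id", "control_id", "distance"])
    return match_cohorts(targets, rest, confounders=confounders,
                         threshold=threshold, age_shift=age_shift,
                         categorical=categorical)


def write_matched(matched: pd.DataFrame, path) -> None:
    matched.to_csv(path, index=False)


def read_matched(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"case_id": str, "control_id": str})
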
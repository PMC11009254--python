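"""ROC/AUC evaluation with correlated-AUC inference.

AUC is computed as the Mann–Whitney U statistic (ties count one half), and
its sampling variance with the DeLong structural-components estimator:
per-positive and per-negative placement values V10 and V01, with

    var(AUC) = var(V10)/n_pos + var(V01)/n_neg .

Two models scored on the *same* subjects yield correlated AUCs; the paired
DeLong test accounts for that correlation through the covariance of the
placement values.  Families of AUCs are screened against chance (0.5) with
Bonferroni-corrected normal confidence intervals, and families of pairwise
comparisons are corrected with the Benjamini–Hochberg FDR step-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests


@dataclass
class EvalResult:
    """ROC points and AUC inference for one model on one dataset."""
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    variance: float | None = None
    ci: tuple[float, float] | None = None
    significant: bool | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"auc": float(self.auc), "n_pos": int(self.n_pos),
             "n_neg": int(self.n_neg)}
        if self.variance is not None:
            d["variance"] = float(self.variance)
        if self.ci is not None:
            d["ci"] = [float(self.ci[0]), float(self.ci[1])]
        if self.significant is not None:
            d["significant"] = bool(self.significant)
        d.update(self.extras)
        return d


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two classes")
    return labels == uniq.max()


def _placement_values(scores: np.ndarray, pos_mask: np.ndarray):
    """Midrank placement values (V10 per positive, V01 per negative) and AUC."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[pos_mask], scores[~pos_mask]
    m, n = len(pos), len(neg)
    r_all = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n            # P(score > random negative)
    v01 = 1.0 - (r_all[m:] - r_neg) / m      # P(random positive > score)
    auc = float(v10.mean())
    return v10, v01, auc


def mann_whitney_auc(scores, labels) -> float:
    """AUC as U/(n_pos·n_neg), ties counted one half."""
    pos_mask = _check_labels(labels)
    return _placement_values(scores, pos_mask)[2]


def roc_auc(scores, labels, with_variance: bool = True) -> EvalResult:
    """ROC curve plus Mann–Whitney AUC (and DeLong variance).

    The trapezoidal area under the returned ROC points equals the
    Mann–Whitney AUC exactly, including under ties.
    """
    pos_mask = _check_labels(labels)
    fpr, tpr, _ = roc_curve(pos_mask.astype(int), scores)
    v10, v01, auc = _placement_values(scores, pos_mask)
    res = EvalResult(fpr=fpr, tpr=tpr, auc=auc,
                     n_pos=int(pos_mask.sum()), n_neg=int((~pos_mask).sum()))
    if with_variance and res.n_pos >= 2 and res.n_neg >= 2:
        res.variance = float(v10.var(ddof=1) / res.n_pos
                             + v01.var(ddof=1) / res.n_neg)
    return res


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimate."""
    pos_mask = _check_labels(labels)
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    v10, v01, _ = _placement_values(scores, pos_mask)
    return float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)


def delong_test_paired(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test of AUC_a = AUC_b on the same subjects.

    Returns (z, p).  Identical score vectors give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must have the same length")
    pos_mask = _check_labels(labels)
    if len(scores_a) != len(pos_mask):
        raise ValueError("scores and labels must have the same length")
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    va10, va01, auc_a = _placement_values(scores_a, pos_mask)
    vb10, vb01, auc_b = _placement_values(scores_b, pos_mask)
    s10 = np.cov(va10, vb10, ddof=1)
    s01 = np.cov(va01, vb01, ddof=1)
    var_diff = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chance_band(auc: float, variance: float, alpha: float = 0.05,
                n_tests: int = 1) -> tuple[tuple[float, float], bool]:
    """Bonferroni-corrected normal CI around an AUC, tested against 0.5.

    The per-test level is ``1 − alpha/n_tests`` (two-sided); the AUC is
    flagged significant iff 0.5 lies outside the corrected interval.
    Returns ``((low, high), significant)``.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    z = sps.norm.ppf(1.0 - alpha / n_tests / 2.0)
    half = z * np.sqrt(variance)
    ci = (float(auc - half), float(auc + half))
    significant = not (ci[0] <= 0.5 <= ci[1])
    return ci, significant


def confusion(scores, labels, threshold: float = 0.5) -> dict:
    """2×2 confusion counts at a score threshold (score ≥ threshold → positive)."""
    pos_mask = _check_labels(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    return {
        "tp": int(np.sum(pred & pos_mask)),
        "fp": int(np.sum(pred & ~pos_mask)),
        "fn": int(np.sum(~pred & pos_mask)),
        "tn": int(np.sum(~pred & ~pos_mask)),
    }


def cross_apply(model, tensor, normalizer=None, alpha: float = 0.05,
                n_tests: int = 1) -> EvalResult:
    """Score a dataset with a frozen model and evaluate the AUC vs chance.

    ``tensor`` is a FeatureTensor; if ``normalizer`` is given (the
    training dataset's z-scoring statistics) it is applied first — a
    frozen model must see inputs on the scale it was trained on.
    """
    if normalizer is not None:
        tensor = normalizer.apply(tensor)
    scores = model.predict_proba(tensor.X)
    res = roc_auc(scores, tensor.y)
    if res.variance is not None:
        res.ci, res.significant = chance_band(res.auc, res.variance,
                                              alpha=alpha, n_tests=n_tests)
    return res
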
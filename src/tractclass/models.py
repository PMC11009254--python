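"""Classifier fitting: the residual CNN and the regularized logistic baseline.

The CNN lives in :mod:`tractclass.nn`; this module adds the L2-regularized
logistic regression trained on the sparse node features, with the
regularization strength chosen on the validation split by AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import evaluation
from .nn import (CnnSpec, ResNet1dClassifier, TrainConfig,  # noqa: F401
                 build_cnn, train_cnn)

#: inverse regularization strengths scanned for the logistic model
DEFAULT_C_GRID = tuple(10.0 ** np.arange(-4.0, 2.5, 0.5))


@dataclass
class LogisticModel:
    """Fitted L2 logistic regression plus the selected strength."""
    estimator: LogisticRegression
    C: float
    validation_auc: float

    def predict_proba(self, F: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(F)[:, 1]

    @property
    def coef_(self) -> np.ndarray:
        return self.estimator.coef_[0]


def fit_logistic_ridge(F_train: np.ndarray, y_train: np.ndarray,
                       F_val: np.ndarray, y_val: np.ndarray,
                       C_grid=DEFAULT_C_GRID) -> LogisticModel:
    """Fit one logistic model per strength; keep the best validation AUC.

    ``C`` is the inverse regularization strength (small C = strong
    penalty).  Ties go to the strongest penalty among the best.  The model
    is refit on the training split only — the validation split is used
    solely for selection.
    """
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        raise ValueError("both splits need both classes")
    if len(C_grid) == 0:
        raise ValueError("empty strength grid")
    best = None
    for C in sorted(C_grid):
        est = LogisticRegression(C=float(C), solver="liblinear", max_iter=1000)
        est.fit(F_train, y_train)
        auc = evaluation.mann_whitney_auc(est.predict_proba(F_val)[:, 1], y_val)
        if best is None or auc > best.validation_auc:
            best = LogisticModel(estimator=est, C=float(C), validation_auc=auc)
    return best
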
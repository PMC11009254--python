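"""Per-bundle model inputs from tract-profile tables.

The classifier input for one bundle is a tensor of subjects × 80 nodes ×
6 channels: the middle 80 of the 100 profile nodes, with one channel per
(tissue property, hemisphere) in the fixed order FA-L, FA-R, MD-L, MD-R,
MK-L, MK-R.  Missing bundles are imputed with the mean profile of the
bundle, computed separately within each split, and tissue properties are
z-scored per (node, channel) with statistics fitted on the training split
only — neither operation ever crosses split boundaries, so no test
information leaks into training.

The logistic baseline uses a sparser featurization: every other node from
the 20th to the 78th (1-based ordinals; 30 nodes) for each of the six
(tissue property, hemisphere) combinations — 180 features per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import NODE_COLUMNS, N_NODES, TISSUE_PROPERTIES, HEMISPHERES

#: channel order of the model input
CHANNELS: tuple[tuple[str, str], ...] = tuple(
    (tp, h) for tp in TISSUE_PROPERTIES for h in HEMISPHERES)
N_CHANNELS = len(CHANNELS)
N_TRIM = 10
N_MODEL_NODES = N_NODES - 2 * N_TRIM  # 80

#: 0-based node indices of the logistic features: 1-based ordinals
#: 20, 22, ..., 78 — every other node from the 20th to the 78th
LOGISTIC_NODE_INDICES = np.arange(19, 78, 2)
N_LOGISTIC_FEATURES = len(LOGISTIC_NODE_INDICES) * N_CHANNELS  # 180


@dataclass
class FeatureTensor:
    """Model input for one bundle: X (n, 80, 6) plus metadata.

    ``missing[i, c]`` flags that subject i's channel c was absent before
    imputation (its X block is NaN until :func:`impute_missing` runs).
    Labels are binary ints (1 = case).
    """
    X: np.ndarray
    missing: np.ndarray
    ids: np.ndarray
    y: np.ndarray
    bundle: str

    def __post_init__(self):
        if self.X.ndim != 3 or self.X.shape[1:] != (N_MODEL_NODES, N_CHANNELS):
            raise ValueError(
                f"feature tensor must be (n, {N_MODEL_NODES}, {N_CHANNELS})")


def _profile_lookup(profiles: pd.DataFrame, bundle: str):
    sub = profiles[profiles["bundle"] == bundle]
    values = {}
    vals = sub[NODE_COLUMNS].to_numpy(dtype=np.float32)
    for row, (sid, tp, hemi, miss) in enumerate(
            zip(sub["subject_id"], sub["tissue_property"],
                sub["hemisphere"], sub["missing"])):
        values[(sid, tp, hemi)] = None if miss else vals[row]
    return values


def assemble_tensor(profiles: pd.DataFrame, bundle: str,
                    subjects: pd.DataFrame,
                    case_label: str = "case") -> FeatureTensor:
    """Stack one bundle's trimmed profiles into an (n, 80, 6) tensor.

    ``subjects`` fixes the roster and labels (rows with ``label ==
    case_label`` get y = 1).  Subjects lacking *every* profile in the
    whole table (all bundles) are excluded with a warning; subjects merely
    missing this bundle stay, flagged for imputation (NaN blocks).
    """
    extant = set(profiles.loc[~profiles["missing"], "subject_id"].unique())
    present = subjects["id"].isin(extant)
    if (~present).any():
        warnings.warn(f"excluding {int((~present).sum())} subject(s) with "
                      "no recognized bundles at all", stacklevel=2)
        subjects = subjects[present].reset_index(drop=True)
    lookup = _profile_lookup(profiles, bundle)
    n = len(subjects)
    X = np.full((n, N_MODEL_NODES, N_CHANNELS), np.nan, dtype=np.float32)
    missing = np.ones((n, N_CHANNELS), dtype=bool)
    for i, sid in enumerate(subjects["id"]):
        for c, (tp, hemi) in enumerate(CHANNELS):
            vals = lookup.get((sid, tp, hemi))
            if vals is not None:
                X[i, :, c] = vals[N_TRIM:N_NODES - N_TRIM]
                missing[i, c] = False
    y = (subjects["label"] == case_label).to_numpy(dtype=np.int64)
    return FeatureTensor(X=X, missing=missing,
                         ids=subjects["id"].to_numpy(), y=y, bundle=bundle)


def assemble_split_tensors(profiles: pd.DataFrame, bundle: str,
                           subjects: pd.DataFrame,
                           splits: pd.DataFrame,
                           case_label: str = "case") -> dict[str, FeatureTensor]:
    """One FeatureTensor per split (subject_id → split from ``splits``)."""
    merged = subjects.merge(splits, left_on="id", right_on="subject_id")
    return {name: assemble_tensor(profiles, bundle,
                                  group.reset_index(drop=True),
                                  case_label=case_label)
            for name, group in merged.groupby("split", sort=True)}


def impute_missing(tensor: FeatureTensor) -> FeatureTensor:
    """Replace missing channel blocks by the split's mean profile.

    Statistics come only from the non-missing subjects of *this* tensor
    (i.e. this split); call separately per split so nothing crosses.
    """
    X = tensor.X.copy()
    for c in range(N_CHANNELS):
        miss = tensor.missing[:, c]
        if miss.all():
            raise ValueError(
                f"channel {CHANNELS[c]} missing for every subject in split")
        if miss.any():
            X[miss, :, c] = X[~miss, :, c].mean(axis=0)
    return replace(tensor, X=X)


@dataclass(frozen=True)
class ZScoreNorm:
    """Per-(node, channel) z-scoring statistics, fitted on one split."""
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, tensor: FeatureTensor) -> FeatureTensor:
        return replace(tensor, X=((tensor.X - self.mean) / self.sd
                                  ).astype(np.float32))


def zscore_fit(train: FeatureTensor) -> ZScoreNorm:
    """Fit per-cell mean/SD on the training tensor (population SD).

    Zero-SD cells are floored at a machine-epsilon-scaled constant (with a
    warning), so constant channels map to zeros rather than NaN.
    """
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0)
    floor = np.finfo(np.float32).eps * np.maximum(1.0, np.abs(mean)) * 10.0
    if np.any(sd <= floor):
        warnings.warn("zero-variance feature cell(s); flooring SD", stacklevel=2)
    sd = np.maximum(sd, floor)
    return ZScoreNorm(mean=mean.astype(np.float32), sd=sd.astype(np.float32))


def zscore_fit_apply(train: FeatureTensor, others: list[FeatureTensor]
                     ) -> tuple[ZScoreNorm, FeatureTensor, list[FeatureTensor]]:
    """Fit on ``train``, apply to train and every other tensor."""
    norm = zscore_fit(train)
    return norm, norm.apply(train), [norm.apply(t) for t in others]


def logistic_features(profiles: pd.DataFrame, bundle: str,
                      subjects: pd.DataFrame,
                      case_label: str = "case"):
    """Sparse node features for the regularized logistic baseline.

    Selects the 1-based node ordinals 20, 22, …, 78 (30 nodes) from each
    of the six (tissue property, hemisphere) profiles — 180 features per
    subject, channel-major in the documented channel order.  Missing
    profiles yield NaN columns; impute per split with
    :func:`impute_feature_matrix`.

    Returns ``(F, missing, ids, y)``.
    """
    if not set(NODE_COLUMNS).issubset(profiles.columns):
        raise ValueError(f"profiles must have {N_NODES} node columns")
    extant = set(profiles.loc[~profiles["missing"], "subject_id"].unique())
    subjects = subjects[subjects["id"].isin(extant)].reset_index(drop=True)
    lookup = _profile_lookup(profiles, bundle)
    n = len(subjects)
    k = len(LOGISTIC_NODE_INDICES)
    F = np.full((n, N_LOGISTIC_FEATURES), np.nan, dtype=float)
    missing = np.ones((n, N_CHANNELS), dtype=bool)
    for i, sid in enumerate(subjects["id"]):
        for c, (tp, hemi) in enumerate(CHANNELS):
            vals = lookup.get((sid, tp, hemi))
            if vals is not None:
                F[i, c * k:(c + 1) * k] = vals[LOGISTIC_NODE_INDICES]
                missing[i, c] = False
    y = (subjects["label"] == case_label).to_numpy(dtype=np.int64)
    return F, missing, subjects["id"].to_numpy(), y


def impute_feature_matrix(F: np.ndarray) -> np.ndarray:
    """Column-mean imputation within one split's feature matrix."""
    F = F.copy()
    col_mean = np.nanmean(F, axis=0)
    idx = np.where(np.isnan(F))
    F[idx] = col_mean[idx[1]]
    return F
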
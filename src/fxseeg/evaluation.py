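"""Performance protocol: stratified 70/30 holdout, ROC/AUC, 10-fold CV.

For each variable set the classifier is trained on a stratified 70% split;
AUC is reported on the withheld 30% and for the model applied back to the
entire dataset (in-sample by construction — flagged as such).  An independent
stratified 10-fold cross-validation gives the classification error, which
protects small subgroups from an unlucky holdout draw.  AUC is rank-based
(the probability a random case outscores a random control, ties counted 1/2),
identical to trapezoidal integration of the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import nbc
from .containers import GROUP_CON, GROUP_FXS, validate_feature_table
from .utils import derive_seed, rng_from


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class random split; train size rounds to the nearest count.

    70 + 71 participants at 0.7 split into 49 + 50 training and 21 + 21 test
    rows.  Deterministic under ``seed``; the two parts are disjoint and
    exhaustive.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train fraction must be in (0, 1]")
    rng = rng_from(seed, "split")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c, sub in table.groupby(group_col, sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        if n_train >= len(idx):
            n_train = min(n_train, len(idx))
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    train = table.loc[np.concatenate(train_idx)].sort_index()
    test_ids = np.concatenate(test_idx)
    if len(test_ids) == 0:
        raise ValueError("train fraction leaves an empty test set")
    test = table.loc[test_ids].sort_index()
    return train, test


def roc_auc(scores, labels, positive: str = GROUP_FXS) -> float:
    """Rank-based AUC: P(score of random positive > score of random negative),
    ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, labels, positive: str = GROUP_FXS) -> pd.DataFrame:
    """Empirical ROC curve points (FPR, TPR), from (0,0) to (1,1)."""
    labels = np.asarray(labels)
    fpr, tpr, thr = _sk_roc_curve(labels == positive, scores, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def trapezoidal_auc(scores, labels, positive: str = GROUP_FXS) -> float:
    pts = roc_points(scores, labels, positive)
    return float(np.trapezoid(pts["tpr"], pts["fpr"]))


def kfold_cv_error(
    table: pd.DataFrame,
    features: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    strict: bool = False,
    group_col: str = "group",
    classes: tuple[str, str] = (GROUP_FXS, GROUP_CON),
) -> float:
    """Stratified k-fold cross-validation classification error.

    If the smaller class has fewer than ``k`` members the fold count is
    reduced to that size (warning), unless ``strict`` is set, in which case
    undersized problems (n < 2k) raise.
    """
    features = validate_feature_table(table, features)
    y = table[group_col].to_numpy()
    if strict and len(table) < 2 * k:
        raise ValueError(f"n={len(table)} too small for {k}-fold CV in strict mode")
    min_class = min(int((y == c).sum()) for c in classes)
    if min_class < k:
        warnings.warn(f"reducing folds from {k} to {min_class} (smallest class size)", stacklevel=2)
        k = min_class
    if k < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, "cv"))
    errors = 0
    for train_ix, test_ix in skf.split(np.zeros(len(table)), y):
        model = nbc.fit(table.iloc[train_ix], features, classes=classes, group_col=group_col)
        pred = nbc.predict(model, table.iloc[test_ix][features])
        errors += int((pred != y[test_ix]).sum())
    return errors / len(table)


@dataclass
class EvalReport:
    """Per-variable-set performance summary (one report row)."""

    name: str
    auc_holdout: float
    auc_full: float
    cv_error: float
    confusion: dict[str, int]  # TP/FP/TN/FN at the 0.5 posterior threshold
    roc: pd.DataFrame
    seed: int
    n: int
    subgroup: str = "all"
    features: list[str] = field(default_factory=list)
    notes: str = "auc_full is in-sample (model applied back to the entire dataset)"

    def validate(self):
        for v in (self.auc_holdout, self.auc_full):
            if not 0.0 <= v <= 1.0:
                raise ValueError("AUC outside [0, 1]")
        if not 0.0 <= self.cv_error <= 1.0:
            raise ValueError("CV error outside [0, 1]")
        if sum(self.confusion.values()) != self.n:
            raise ValueError("confusion counts must sum to n")
        fpr, tpr = self.roc["fpr"].to_numpy(), self.roc["tpr"].to_numpy()
        if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
            raise ValueError("ROC must run from (0,0) to (1,1)")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")
        return self


def evaluate_variable_set(
    table: pd.DataFrame,
    features: list[str] | None = None,
    seed: int = 0,
    name: str = "",
    subgroup: str = "all",
    confusion_on: str = "full",
    classes: tuple[str, str] = (GROUP_FXS, GROUP_CON),
    group_col: str = "group",
) -> EvalReport:
    """Run the full protocol for one variable set.

    Fits on the stratified 70% split, reports holdout AUC on the 30%, then
    applies the same model back to all rows for the full-dataset AUC, ROC
    curve and confusion matrix, and finally runs an independent seeded
    10-fold CV pass for the error rate.
    """
    features = validate_feature_table(table, features)
    train, test = stratified_split(table, 0.7, seed=seed, group_col=group_col)
    model = nbc.fit(train, features, classes=classes, group_col=group_col)

    p_test = np.atleast_1d(nbc.posterior(model, test[features]))
    auc_holdout = roc_auc(p_test, test[group_col].to_numpy(), positive=classes[0])

    p_full = np.atleast_1d(nbc.posterior(model, table[features]))
    y_full = table[group_col].to_numpy()
    auc_full = roc_auc(p_full, y_full, positive=classes[0])
    roc = roc_points(p_full, y_full, positive=classes[0])

    if confusion_on == "full":
        p_conf, y_conf = p_full, y_full
    elif confusion_on == "holdout":
        p_conf, y_conf = p_test, test[group_col].to_numpy()
    else:
        raise ValueError(f"unknown confusion_on {confusion_on!r}")
    pred_pos = p_conf > 0.5
    actual_pos = y_conf == classes[0]
    confusion = {
        "TP": int((pred_pos & actual_pos).sum()),
        "FP": int((pred_pos & ~actual_pos).sum()),
        "TN": int((~pred_pos & ~actual_pos).sum()),
        "FN": int((~pred_pos & actual_pos).sum()),
    }

    cv = kfold_cv_error(table, features, k=10, seed=derive_seed(seed, "cvpass"),
                        group_col=group_col, classes=classes)
    n_conf = len(y_conf)
    return EvalReport(
        name=name or "+".join(features),
        auc_holdout=auc_holdout,
        auc_full=auc_full,
        cv_error=cv,
        confusion=confusion,
        roc=roc,
        seed=seed,
        n=n_conf,
        subgroup=subgroup,
        features=list(features),
    ).validate()
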
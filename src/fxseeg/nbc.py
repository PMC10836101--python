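"""Gaussian naive Bayes classifier with fixed equal priors.

The study's sole learning machine, written from scratch: per class and
feature, a univariate Gaussian fitted by maximum likelihood; class priors
fixed at 0.5 each (an override exists but group sizes were approximately
balanced).  The posterior of the case class, computed in log space with a
variance floor for near-constant features, is the score fed to ROC analysis.
Each feature contributes an additive log-likelihood-ratio term, so the
decision function is a linear combination of per-feature evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import GROUP_CON, GROUP_FXS, validate_feature_table

logger = logging.getLogger(__name__)

VAR_FLOOR_ABS = 1e-12
VAR_FLOOR_REL = 1e-9  # times the pooled feature variance


@dataclass
class NBCModel:
    """Per-class, per-feature Gaussian parameters plus fixed priors."""

    classes: tuple[str, str]  # (positive/case class, negative/control class)
    feature_names: list[str]
    means: np.ndarray  # (2, n_features)
    variances: np.ndarray  # (2, n_features), floored > 0
    priors: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive (floored)")
        if self.means.shape != (2, len(self.feature_names)):
            raise ValueError("means shape must be (2, n_features)")

    @property
    def positive(self) -> str:
        return self.classes[0]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "priors": [float(p) for p in self.priors],
            "features": {
                name: {
                    c: {"mean": float(self.means[i, j]), "variance": float(self.variances[i, j])}
                    for i, c in enumerate(self.classes)
                }
                for j, name in enumerate(self.feature_names)
            },
        }

    def save(self, path) -> None:
        """Serialize to a human-readable YAML document for audit."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NBCModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        names = list(d["features"])
        classes = tuple(d["classes"])
        means = np.array([[d["features"][f][c]["mean"] for f in names] for c in classes])
        var = np.array([[d["features"][f][c]["variance"] for f in names] for c in classes])
        return cls(classes, names, means, var, np.array(d["priors"]))


def fit(
    table: pd.DataFrame,
    features: list[str] | None = None,
    classes: tuple[str, str] = (GROUP_FXS, GROUP_CON),
    priors: tuple[float, float] = (0.5, 0.5),
    ddof: int = 1,
    group_col: str = "group",
) -> NBCModel:
    """Fit per-class Gaussians by maximum likelihood.

    Class means are sample means; variances use denominator ``n - ddof``
    (unbiased by default) and are floored at
    ``max(1e-12, 1e-9 * pooled feature variance)`` so that features constant
    within a class cannot produce degenerate likelihoods.
    """
    features = validate_feature_table(table, features)
    X = table[features].to_numpy(dtype=float)
    y = table[group_col].to_numpy()
    means = np.empty((2, len(features)))
    var = np.empty((2, len(features)))
    pooled = X.var(axis=0, ddof=0)
    floor = np.maximum(VAR_FLOOR_ABS, VAR_FLOOR_REL * pooled)
    for i, c in enumerate(classes):
        sel = y == c
        if sel.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[i] = X[sel].mean(axis=0)
        var[i] = X[sel].var(axis=0, ddof=ddof)
    degenerate = var <= floor
    if degenerate.any():
        bad = sorted({features[j] for j in np.where(degenerate.any(axis=0))[0]})
        warnings.warn(f"variance floored for near-constant features: {bad}", stacklevel=2)
    var = np.maximum(var, floor)
    return NBCModel(classes, list(features), means, var, np.asarray(priors, dtype=float))


def _as_matrix(model: NBCModel, x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        X = x[model.feature_names].to_numpy(dtype=float)
    elif isinstance(x, pd.Series):
        X = x[model.feature_names].to_numpy(dtype=float)[None, :]
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ValueError(f"expected {len(model.feature_names)} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def posterior(model: NBCModel, x) -> np.ndarray | float:
    """Posterior probability of the case (first) class.

    log p(c|x) = log pi_c + sum_f log N(x_f; mu_cf, var_cf) up to the shared
    normalizer, evaluated with log-sum-exp.  Returns a float for a single
    sample, an array for a matrix/table of samples.
    """
    X = _as_matrix(model, x)
    log_joint = np.empty((X.shape[0], 2))
    for i in range(2):
        mu, v = model.means[i], model.variances[i]
        ll = -0.5 * (np.log(2 * np.pi * v) + (X - mu) ** 2 / v).sum(axis=1)
        log_joint[:, i] = np.log(model.priors[i]) + ll
    m = log_joint.max(axis=1, keepdims=True)
    norm = m[:, 0] + np.log(np.exp(log_joint - m).sum(axis=1))
    p = np.exp(log_joint[:, 0] - norm)
    single = isinstance(x, (pd.Series, list)) or (hasattr(x, "ndim") and getattr(x, "ndim", 2) == 1)
    if single and p.shape[0] == 1:
        return float(p[0])
    return p


def predict(model: NBCModel, x):
    """Argmax-posterior labels; an exact 0.5 tie goes to the control class."""
    p = posterior(model, x)
    if np.isscalar(p):
        return model.classes[0] if p > 0.5 else model.classes[1]
    return np.where(p > 0.5, model.classes[0], model.classes[1])
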
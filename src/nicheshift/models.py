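"""Niche learner family.

Three algorithm classes spanning parametric, envelope, and flexible learners:

* ``glm`` — regularized logistic regression on standardized linear plus
  quadratic terms per variable, the classic parametric response-curve model.
* ``sre`` — rectilinear surface range envelope: suitability 1 inside the
  per-variable presence quantile box [q, 1−q], 0 outside (q = 0.025).
* ``gbm`` — gradient-boosted shallow trees (xgboost histogram method).

Every learner exposes ``predict(X) -> suitability in [0, 1]`` on a DataFrame
with the training variables as columns, and is deterministic given the
training table and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from .errors import ConfigurationError

ALGORITHMS = ("glm", "sre", "gbm")


def _drop_constant(X: pd.DataFrame) -> list[str]:
    """Names of non-degenerate columns; warns about dropped constants."""
    keep = []
    for c in X.columns:
        if np.ptp(X[c].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"variable {c!r} is constant in the training table; dropped")
        else:
            keep.append(c)
    if not keep:
        raise ConfigurationError("all variables constant; cannot fit")
    return keep


@dataclass
class FittedModel:
    """A fitted niche learner.

    ``variables`` are the columns the model consumes; ``predict`` maps a
    DataFrame containing them to suitabilities in [0, 1].
    """

    algorithm_id: str
    variables: list[str]
    _impl: object = dataclass_field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise ConfigurationError(f"prediction input lacks variables {missing}")
        return self._impl(X[self.variables])


class _GlmImpl:
    def __init__(self, X: pd.DataFrame, y: np.ndarray):
        arr = X.to_numpy(dtype=float)
        self.mean = arr.mean(axis=0)
        self.std = arr.std(axis=0)
        self.std[self.std == 0] = 1.0
        z = (arr - self.mean) / self.std
        feats = np.hstack([z, z**2])
        self.clf = LogisticRegression(C=1.0, max_iter=1000)
        self.clf.fit(feats, y)

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        z = (X.to_numpy(dtype=float) - self.mean) / self.std
        return self.clf.predict_proba(np.hstack([z, z**2]))[:, 1]


class _SreImpl:
    """Presence-quantile hyper-rectangle at quantile q."""

    def __init__(self, X: pd.DataFrame, y: np.ndarray, q: float = 0.025):
        pres = X.to_numpy(dtype=float)[np.asarray(y) == 1]
        self.lo = np.quantile(pres, q, axis=0)
        self.hi = np.quantile(pres, 1.0 - q, axis=0)

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        arr = X.to_numpy(dtype=float)
        inside = (arr >= self.lo) & (arr <= self.hi)
        return inside.all(axis=1).astype(float)


class _GbmImpl:
    def __init__(self, X: pd.DataFrame, y: np.ndarray, seed: int):
        self.clf = XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1,
            tree_method="hist", n_jobs=1, random_state=int(seed) % (2**31),
            verbosity=0, eval_metric="logloss",
        )
        self.clf.fit(X.to_numpy(dtype=float), np.asarray(y))

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        return self.clf.predict_proba(X.to_numpy(dtype=float))[:, 1].astype(float)


def fit_model(
    algorithm_id: str,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    sre_quantile: float = 0.025,
) -> FittedModel:
    """Fit one learner on a presence(1)/pseudoabsence(0) design matrix."""
    if algorithm_id not in ALGORITHMS:
        raise ConfigurationError(
            f"unknown algorithm {algorithm_id!r}; available: {ALGORITHMS}"
        )
    y = np.asarray(y)
    variables = _drop_constant(X)
    Xk = X[variables]
    if algorithm_id == "glm":
        impl = _GlmImpl(Xk, y)
    elif algorithm_id == "sre":
        impl = _SreImpl(Xk, y, q=sre_quantile)
    else:
        impl = _GbmImpl(Xk, y, seed)
    return FittedModel(algorithm_id=algorithm_id, variables=variables, _impl=impl)
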
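"""Per-stage proportion regression with simplex normalisation.

Four independent scalar regressors — one per macro stage (Wake, Light = N1+N2,
Deep = N3, REM) — map the shared 76-dimensional episode feature vector to raw
stage proportions, which are then projected onto the probability simplex via

    p_hat_s = max(eps, p_raw_s) / sum_s' max(eps, p_raw_s'),

with a small eps > 0 (default 1e-6) guarding against negative or all-zero raw
outputs.  Targets are proportions of total recording time derived from the
30 s-epoch hypnogram.  The regressor inventory mirrors the standard tabular
suite (linear, tree, forest, SVR, kNN, shallow MLP) with fixed published
hyperparameters, plus an optional TabPFN adapter behind the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.ensemble import RandomForestRegressor

from .errors import (
    ConfigurationError,
    InvalidArgumentError,
    NumericError,
    StateError,
)
from .features import feature_names

__all__ = [
    "STAGE_NAMES",
    "HYPNOGRAM_LABELS",
    "StageProportions",
    "StageModelBundle",
    "simplex_normalize",
    "hypnogram_to_proportions",
    "fit_stage_models",
    "predict_proportions",
]

#: The four macro stages, in fixed order.
STAGE_NAMES: Tuple[str, str, str, str] = ("wake", "light", "deep", "rem")

#: Valid 30 s-epoch hypnogram labels and their macro-stage mapping.
HYPNOGRAM_LABELS: Dict[str, str] = {
    "W": "wake",
    "N1": "light",
    "N2": "light",
    "N3": "deep",
    "REM": "rem",
}

DEFAULT_EPSILON = 1e-6

#: Regressors needing feature standardisation (fit-set statistics) first.
_SCALED_KINDS = {"svr", "knn", "mlp"}


@dataclass
class StageProportions:
    """A point on the 4-simplex: fractions of recording time per macro stage."""

    wake: float
    light: float
    deep: float
    rem: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0):
            raise InvalidArgumentError("stage proportions must be nonnegative")
        if abs(float(arr.sum()) - 1.0) > 1e-12:
            raise InvalidArgumentError("stage proportions must sum to 1 within 1e-12")

    def as_array(self) -> np.ndarray:
        return np.array([self.wake, self.light, self.deep, self.rem], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StageProportions":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise InvalidArgumentError("stage proportions need exactly 4 entries")
        return cls(*(float(v) for v in arr))

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(STAGE_NAMES, self.as_array().tolist()))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def simplex_normalize(raw, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Project raw stage predictions onto the simplex via max(eps, .)/sum."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        bad = [STAGE_NAMES[i] for i in np.flatnonzero(~np.isfinite(raw))]
        raise NumericError(f"non-finite raw prediction for stage(s): {', '.join(bad)}")
    if epsilon <= 0:
        raise InvalidArgumentError("epsilon must be positive")
    clipped = np.maximum(epsilon, raw)
    return clipped / clipped.sum()


def hypnogram_to_proportions(hypnogram: Sequence[str]) -> StageProportions:
    """Epoch-count proportions of the four macro stages (N1+N2 merged)."""
    labels = list(hypnogram)
    if not labels:
        raise InvalidArgumentError("hypnogram is empty")
    counts = dict.fromkeys(STAGE_NAMES, 0)
    for lab in labels:
        key = str(lab)
        if key not in HYPNOGRAM_LABELS:
            raise InvalidArgumentError(f"unknown hypnogram label: {key!r}")
        counts[HYPNOGRAM_LABELS[key]] += 1
    n = len(labels)
    return StageProportions(**{s: counts[s] / n for s in STAGE_NAMES})


def _make_regressor(kind: str, seed: Optional[int], standardize: bool):
    """Instantiate one scalar regressor with the fixed hyperparameter set."""
    kind = kind.lower()
    if kind == "lr":
        est = LinearRegression(fit_intercept=True, positive=False)
    elif kind == "dtr":
        est = DecisionTreeRegressor(
            criterion="squared_error",
            max_depth=None,
            min_samples_split=2,
            min_samples_leaf=1,
            random_state=seed,
        )
    elif kind == "rfr":
        est = RandomForestRegressor(
            n_estimators=100,
            max_depth=None,
            min_samples_leaf=1,
            bootstrap=True,
            random_state=seed,
        )
    elif kind == "svr":
        est = SVR(C=1.0, epsilon=0.1, kernel="rbf", gamma="scale")
    elif kind == "knn":
        est = KNeighborsRegressor(n_neighbors=5, weights="uniform", metric="minkowski")
    elif kind == "mlp":
        est = MLPRegressor(
            hidden_layer_sizes=(100,),
            activation="relu",
            solver="adam",
            alpha=1e-4,
            learning_rate="adaptive",
            max_iter=1000,
            random_state=seed,
        )
    elif kind == "tabpfn":
        try:
            from tabpfn import TabPFNRegressor  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigurationError(
                "regressor_kind 'tabpfn' requires the optional tabpfn package"
            ) from exc
        est = TabPFNRegressor()  # pragma: no cover
    else:
        raise ConfigurationError(f"unknown regressor_kind: {kind!r}")
    if standardize and kind in _SCALED_KINDS:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


@dataclass
class StageModelBundle:
    """Four fitted per-stage regressors sharing one kind and feature order."""

    regressor_kind: str
    models: Dict[str, object]
    feature_order: Tuple[str, ...]
    epsilon: float = DEFAULT_EPSILON
    standardize: bool = True
    seed: Optional[int] = None

    @property
    def is_fitted(self) -> bool:
        return len(self.models) == len(STAGE_NAMES)


def _check_features(X: pd.DataFrame, expected: Sequence[str]) -> np.ndarray:
    if list(X.columns) != list(expected):
        missing = set(expected) - set(X.columns)
        extra = set(X.columns) - set(expected)
        raise ConfigurationError(
            "feature columns do not match the expected feature order "
            f"(missing: {sorted(missing)[:5]}, unexpected: {sorted(extra)[:5]})"
        )
    return X.to_numpy(float)


def fit_stage_models(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    regressor_kind: str = "rfr",
    seed: Optional[int] = 0,
    standardize: bool = True,
    epsilon: float = DEFAULT_EPSILON,
    feature_order: Optional[Sequence[str]] = None,
) -> StageModelBundle:
    """Fit one scalar regressor per stage on a (subjects x features) table.

    ``X`` columns must match ``feature_order`` (default: the canonical 76
    names); ``Y`` must contain one column per macro stage.  Stochastic
    learners are seeded; SVR/kNN/MLP inputs are standardised with fit-set
    statistics unless ``standardize`` is disabled.
    """
    if feature_order is None:
        feature_order = feature_names()
    if len(X) < 2:
        raise InvalidArgumentError("need at least 2 training subjects")
    if len(X) != len(Y):
        raise InvalidArgumentError("X and Y must have the same number of rows")
    missing = [s for s in STAGE_NAMES if s not in Y.columns]
    if missing:
        raise ConfigurationError(f"target table lacks stage columns: {missing}")
    Xmat = _check_features(X, feature_order)
    models: Dict[str, object] = {}
    for stage in STAGE_NAMES:
        est = _make_regressor(regressor_kind, seed, standardize)
        models[stage] = est.fit(Xmat, Y[stage].to_numpy(float))
    return StageModelBundle(
        regressor_kind=regressor_kind.lower(),
        models=models,
        feature_order=tuple(feature_order),
        epsilon=epsilon,
        standardize=standardize,
        seed=seed,
    )


def predict_proportions(bundle: StageModelBundle, x) -> StageProportions:
    """Predict one subject's stage proportions and project onto the simplex."""
    if not bundle.is_fitted:
        raise StateError("stage model bundle is not fitted")
    arr = _coerce_features(bundle, x)
    raw = np.array(
        [float(bundle.models[s].predict(arr[None, :])[0]) for s in STAGE_NAMES]
    )
    return StageProportions.from_array(simplex_normalize(raw, bundle.epsilon))


def predict_proportions_table(bundle: StageModelBundle, X: pd.DataFrame) -> pd.DataFrame:
    """Vectorised prediction for a feature table; one simplex row per subject."""
    if not bundle.is_fitted:
        raise StateError("stage model bundle is not fitted")
    Xmat = _check_features(X, bundle.feature_order)
    raw = np.column_stack(
        [np.asarray(bundle.models[s].predict(Xmat), dtype=float) for s in STAGE_NAMES]
    )
    out = np.vstack([simplex_normalize(r, bundle.epsilon) for r in raw])
    return pd.DataFrame(out, columns=list(STAGE_NAMES), index=X.index)


def _coerce_features(bundle: StageModelBundle, x) -> np.ndarray:
    from .features import EpisodeFeatureVector

    if isinstance(x, EpisodeFeatureVector):
        if x.names != bundle.feature_order:
            raise ConfigurationError("feature vector names do not match the bundle")
        return x.values
    if isinstance(x, pd.Series):
        if list(x.index) != list(bundle.feature_order):
            raise ConfigurationError("feature series index does not match the bundle")
        return x.to_numpy(float)
    arr = np.asarray(x, dtype=float)
    if arr.shape != (len(bundle.feature_order),):
        raise InvalidArgumentError(
            f"expected a {len(bundle.feature_order)}-vector of features"
        )
    return arr
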
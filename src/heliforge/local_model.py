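"""Per-query local random-forest regression and its evaluation protocol.

The predictor at the heart of the package: for each query molecule, the
k nearest training molecules under a weighted Euclidean distance on the
16-element Hammett descriptor vector are retrieved, and one random
forest per property is fitted on that neighbourhood only. A conventional
global forest trained on the whole pool serves as the baseline it is
compared against.

Both predictors are scikit-learn style estimators
(:class:`LocalForestRegressor`, :class:`GlobalForestRegressor`) and
compose with sklearn tooling; the module-level functions
(:func:`fit_predict_local`, :func:`fit_predict_global`,
:func:`evaluate`) are thin wrappers speaking the package's Dataset /
PropertyRecord vocabulary.

Evaluation reports MAE and RMSE per property and flags outliers by the
robust rule: a residual is an outlier when it deviates from the median
residual by more than 2.5 times the scaled median absolute deviation
(MAD x 1.4826, the normal-consistency scaling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from ._seeds import derive_seed
from .chem_space import HeliceneMolecule, encode, format_name
from .chiroptics import PROPERTY_NAMES, PropertyRecord
from .dataset_io import Dataset
from .errors import DimensionError, InsufficientPoolError

__all__ = [
    "DEFAULT_FOREST_PARAMS",
    "LocalForestRegressor",
    "GlobalForestRegressor",
    "EvalReport",
    "weighted_distance",
    "nearest_neighbours",
    "fit_predict_local",
    "fit_predict_global",
    "evaluate",
    "LocalModelPredictor",
]

logger = logging.getLogger(__name__)

#: Robust small-sample forest defaults; all overridable per call.
DEFAULT_FOREST_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": None,
    "max_features": "sqrt",
}

MAD_SCALE = 1.4826  # normal-consistency constant for the scaled MAD
OUTLIER_FACTOR = 2.5


def weighted_distance(
    a: Sequence[float], b: Sequence[float], w: Sequence[float] | None = None
) -> float:
    """sqrt(sum w_i (a_i - b_i)^2); a metric for strictly positive w."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    if w is None:
        w = np.ones_like(a)
    w = np.asarray(w, dtype=float)
    if w.shape != a.shape:
        raise DimensionError(f"weights length mismatch: {w.shape} vs {a.shape}")
    if np.any(w < 0) or not np.all(np.isfinite(w)) or not np.any(w > 0):
        raise ValueError("weights must be finite, non-negative, not all zero")
    return float(np.sqrt(np.sum(w * (a - b) ** 2)))


def _pairwise_wdist(Q: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(n_queries, n_pool) weighted Euclidean distances."""
    diff = Q[:, None, :] - X[None, :, :]
    return np.sqrt(np.einsum("qpd,d->qp", diff * diff, w))


class LocalForestRegressor(BaseEstimator, RegressorMixin):
    """Per-query k-nearest-neighbour random-forest regressor.

    fit() only memorises the training pool; all regression work happens
    at predict() time, when a fresh forest per target column is trained
    on each query's neighbourhood. Neighbour order is deterministic:
    ties in distance break on canonical name (or pool index when names
    are absent), and the forest seed derives from ``random_state`` and
    the query name.

    Parameters
    ----------
    k : neighbourhood size (the 100 default gave the best regression
        performance across properties in the motivating protocol).
    weights : per-feature distance weights, default uniform.
    n_estimators, max_depth, max_features : forest hyper-parameters.
    clamp : {column index: (lo, hi)} interval clamps applied to
        predictions, used to keep g_abs inside its physical [-2, 2].
    random_state : seed for all forests.
    """

    def __init__(
        self,
        k: int = 100,
        weights: Sequence[float] | None = None,
        n_estimators: int = 100,
        max_depth: int | None = None,
        max_features: str | int | float = "sqrt",
        clamp: Mapping[int, tuple[float, float]] | None = None,
        random_state: int = 0,
    ):
        self.k = k
        self.weights = weights
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.clamp = clamp
        self.random_state = random_state

    def fit(self, X, y, names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise DimensionError("X and y have different lengths")
        self.X_ = X
        self.y_ = y
        self.names_ = list(names) if names is not None else [str(i) for i in range(len(X))]
        self.n_features_in_ = X.shape[1]
        self.n_targets_ = y.shape[1]
        w = np.ones(X.shape[1]) if self.weights is None else np.asarray(self.weights, float)
        if w.shape != (X.shape[1],):
            raise DimensionError("weights must match the feature dimension")
        self.w_ = w
        return self

    def kneighbors(self, x: np.ndarray, exclude_name: str | None = None) -> np.ndarray:
        """Indices of the k nearest pool rows for one query vector."""
        check_is_fitted(self, "X_")
        d = _pairwise_wdist(np.asarray(x, float)[None, :], self.X_, self.w_)[0]
        mask = np.ones(len(d), dtype=bool)
        if exclude_name is not None:
            mask &= np.array([n != exclude_name for n in self.names_])
        avail = np.flatnonzero(mask)
        if self.k > len(avail):
            raise InsufficientPoolError(
                f"k={self.k} exceeds available pool of {len(avail)}"
            )
        order = sorted(avail, key=lambda i: (d[i], self.names_[i]))
        return np.array(order[: self.k], dtype=int)

    def predict(
        self,
        X,
        names: Sequence[str] | None = None,
        columns: Sequence[int] | None = None,
    ) -> np.ndarray:
        """Predict target columns for each query row.

        ``names`` enables the leakage guard: a pool row with the same
        name as the query is excluded from its own neighbourhood.
        ``columns`` restricts prediction to a subset of target columns
        (the others return NaN).
        """
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        cols = list(range(self.n_targets_)) if columns is None else list(columns)
        out = np.full((len(X), self.n_targets_), np.nan)
        for qi, x in enumerate(X):
            qname = names[qi] if names is not None else None
            idx = self.kneighbors(x, exclude_name=qname)
            Xn, yn = self.X_[idx], self.y_[idx]
            degenerate = bool(np.all(Xn == Xn[0]))
            if degenerate:
                logger.warning(
                    "degenerate neighbourhood for query %s: predicting the mean",
                    qname or qi,
                )
            for c in cols:
                if degenerate:
                    out[qi, c] = float(np.mean(yn[:, c]))
                    continue
                seed = derive_seed(self.random_state, "local-rf", qname or qi, c)
                rf = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    max_depth=self.max_depth,
                    max_features=self.max_features,
                    random_state=seed,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rf.fit(Xn, yn[:, c])
                out[qi, c] = float(rf.predict(x[None, :])[0])
        if self.clamp:
            for c, (lo, hi) in self.clamp.items():
                out[:, c] = np.clip(out[:, c], lo, hi)
        return out


class GlobalForestRegressor(BaseEstimator, RegressorMixin):
    """One random forest per property, trained on the full pool.

    The conventional baseline the local approach is measured against.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        max_features: str | int | float = "sqrt",
        clamp: Mapping[int, tuple[float, float]] | None = None,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.clamp = clamp
        self.random_state = random_state

    def fit(self, X, y, columns: Sequence[int] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) == 0:
            raise InsufficientPoolError("empty training pool")
        self.n_targets_ = y.shape[1]
        self.fitted_columns_ = (
            list(range(self.n_targets_)) if columns is None else list(columns)
        )
        self.forests_ = {}
        for c in self.fitted_columns_:
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                max_features=self.max_features,
                random_state=derive_seed(self.random_state, "global-rf", c),
            )
            rf.fit(X, y[:, c])
            self.forests_[c] = rf
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forests_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = np.full((len(X), self.n_targets_), np.nan)
        for c, rf in self.forests_.items():
            out[:, c] = rf.predict(X)
        if self.clamp:
            for c, (lo, hi) in self.clamp.items():
                if c in self.forests_:
                    out[:, c] = np.clip(out[:, c], lo, hi)
        return out


def _g_clamp() -> dict[int, tuple[float, float]]:
    return {PROPERTY_NAMES.index("g_abs"): (-2.0, 2.0)}


def nearest_neighbours(
    query: HeliceneMolecule,
    pool: Dataset,
    k: int,
    w: Sequence[float] | None = None,
) -> list[tuple[str, float]]:
    """The k nearest pool molecules to the query, as (name, distance).

    The query itself (matched by canonical name) never appears in its
    own neighbourhood; exact distance ties break on name order.
    """
    feats = pool.features()
    qv = encode(query)
    wv = np.ones(feats.shape[1]) if w is None else np.asarray(w, float)
    d = _pairwise_wdist(qv[None, :], feats, wv)[0]
    qname = format_name(query)
    entries = [(n, float(di)) for n, di in zip(pool.names, d) if n != qname]
    if k > len(entries):
        raise InsufficientPoolError(f"k={k} exceeds available pool of {len(entries)}")
    entries.sort(key=lambda t: (t[1], t[0]))
    return entries[:k]


def fit_predict_local(
    query: HeliceneMolecule,
    pool: Dataset,
    k: int = 100,
    w: Sequence[float] | None = None,
    forest_params: Mapping | None = None,
    seed: int = 0,
    properties: Sequence[str] | None = None,
) -> PropertyRecord | dict[str, float]:
    """Predict a query molecule's properties from its local neighbourhood.

    Returns a full :class:`PropertyRecord` when all nine properties are
    requested (the default), otherwise a {property: value} dict.
    """
    fp = dict(DEFAULT_FOREST_PARAMS, **(forest_params or {}))
    est = LocalForestRegressor(
        k=k, weights=w, clamp=_g_clamp(), random_state=seed, **fp
    )
    est.fit(pool.features(), pool.targets(), names=pool.names)
    cols = (
        None
        if properties is None
        else [PROPERTY_NAMES.index(p) for p in properties]
    )
    row = est.predict(encode(query)[None, :], names=[format_name(query)], columns=cols)[0]
    if properties is None:
        return PropertyRecord.from_array(row)
    return {p: float(row[PROPERTY_NAMES.index(p)]) for p in properties}


def fit_predict_global(
    pool: Dataset,
    queries: Sequence[HeliceneMolecule] | Dataset,
    forest_params: Mapping | None = None,
    seed: int = 0,
    properties: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Global-forest predictions for a batch of queries.

    Returns a DataFrame indexed by query name with one column per
    predicted property.
    """
    fp = dict(DEFAULT_FOREST_PARAMS, **(forest_params or {}))
    cols = (
        list(range(len(PROPERTY_NAMES)))
        if properties is None
        else [PROPERTY_NAMES.index(p) for p in properties]
    )
    est = GlobalForestRegressor(clamp=_g_clamp(), random_state=seed, **fp)
    est.fit(pool.features(), pool.targets(), columns=cols)
    if isinstance(queries, Dataset):
        Q = queries.features()
        names = queries.names
    else:
        Q = np.array([encode(m) for m in queries])
        names = [format_name(m) for m in queries]
    pred = est.predict(Q)
    out = pd.DataFrame(pred, columns=list(PROPERTY_NAMES), index=names)
    return out.iloc[:, cols]


@dataclass
class EvalReport:
    """Per-property regression metrics plus the residual table."""

    metrics: dict[str, dict]
    residuals: pd.DataFrame  # columns: name, property, predicted, true, residual, outlier

    def to_json_dict(self) -> dict:
        return {
            p: {
                "mae": m["mae"],
                "rmse": m["rmse"],
                "outlier_fraction": m["outlier_fraction"],
                "outlier_names": list(m["outlier_names"]),
            }
            for p, m in self.metrics.items()
        }

    def max_outlier_fraction(self) -> float:
        return max(m["outlier_fraction"] for m in self.metrics.values())


def mad_outliers(residuals: np.ndarray) -> np.ndarray:
    """Boolean outlier mask under the 2.5 x scaled-MAD rule.

    A point is flagged when its residual deviates from the median
    residual by more than ``2.5 * 1.4826 * median(|r - median(r)|)``.
    """
    r = np.asarray(residuals, dtype=float)
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    return np.abs(r - med) > OUTLIER_FACTOR * MAD_SCALE * mad


def evaluate(
    predictions: pd.DataFrame | np.ndarray,
    truths: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
    properties: Sequence[str] | None = None,
) -> EvalReport:
    """MAE, RMSE and scaled-MAD outlier statistics per property."""
    P = np.asarray(predictions, dtype=float)
    T = np.asarray(truths, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if T.ndim == 1:
        T = T[:, None]
    if P.shape != T.shape:
        raise DimensionError(f"shape mismatch: {P.shape} vs {T.shape}")
    if len(P) < 2:
        raise DimensionError("need at least two points to evaluate")
    if properties is None:
        if isinstance(predictions, pd.DataFrame):
            properties = list(predictions.columns)
        else:
            properties = [f"y{c}" for c in range(P.shape[1])]
    if names is None:
        if isinstance(predictions, pd.DataFrame):
            names = list(predictions.index.astype(str))
        else:
            names = [str(i) for i in range(len(P))]

    metrics: dict[str, dict] = {}
    frames = []
    for c, prop in enumerate(properties):
        r = P[:, c] - T[:, c]
        out = mad_outliers(r)
        metrics[prop] = {
            "mae": float(np.mean(np.abs(r))),
            "rmse": float(np.sqrt(np.mean(r**2))),
            "outlier_fraction": float(np.mean(out)),
            "outlier_names": [n for n, o in zip(names, out) if o],
        }
        frames.append(
            pd.DataFrame(
                {
                    "name": names,
                    "property": prop,
                    "predicted": P[:, c],
                    "true": T[:, c],
                    "residual": r,
                    "outlier": out,
                }
            )
        )
    return EvalReport(metrics=metrics, residuals=pd.concat(frames, ignore_index=True))


class LocalModelPredictor:
    """molecule -> PropertyRecord predictor backed by local forests.

    The plug-in used by the genetic algorithm and the iterative loop:
    it fits one local model per queried molecule against a fixed pool
    dataset and caches results by canonical name. Properties outside
    ``properties`` (when given) are filled from the pool median so the
    returned record is always complete and physically valid.
    """

    def __init__(
        self,
        pool: Dataset,
        k: int = 100,
        w: Sequence[float] | None = None,
        forest_params: Mapping | None = None,
        seed: int = 0,
        properties: Sequence[str] | None = None,
    ):
        self.pool = pool
        self.k = min(k, max(1, len(pool) - 1))
        self.w = w
        fp = dict(DEFAULT_FOREST_PARAMS, **(forest_params or {}))
        self.est = LocalForestRegressor(
            k=self.k, weights=w, clamp=_g_clamp(), random_state=seed, **fp
        )
        self.est.fit(pool.features(), pool.targets(), names=pool.names)
        self.properties = list(properties) if properties is not None else None
        self._fill = np.median(pool.targets(), axis=0)
        self._cache: dict[str, PropertyRecord] = {}

    def __call__(self, mol: HeliceneMolecule) -> PropertyRecord:
        name = format_name(mol)
        if name not in self._cache:
            cols = (
                None
                if self.properties is None
                else [PROPERTY_NAMES.index(p) for p in self.properties]
            )
            row = self.est.predict(encode(mol)[None, :], names=[name], columns=cols)[0]
            if cols is not None:
                filled = self._fill.copy()
                filled[cols] = row[cols]
                row = filled
            self._cache[name] = PropertyRecord.from_array(row)
        return self._cache[name]
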
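"""Prediction models: mean baseline, bimodal kNN, feed-forward network, and
a registry of standard single-drug regressors.

Pan-drug estimators follow scikit-learn conventions and operate on
(sample, drug) pair rows whose feature vector is the concatenation of the
drug fingerprint and the sample's gene-expression profile (built by
:func:`build_pair_dataset`). The zero-filled-omics ablation — replacing every
expression vector with zeros to probe whether a model uses molecular
features at all — is a constructor flag.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import DrugFeatureSet, ResponseMatrix

__all__ = [
    "tanimoto_similarity",
    "build_pair_dataset",
    "DrugMeanRegressor",
    "BimodalKNNRegressor",
    "FeedForwardRegressor",
    "REGRESSOR_REGISTRY",
    "make_single_drug_regressor",
    "single_drug_fit_predict",
    "linear_model_to_json",
]

logger = logging.getLogger(__name__)


def tanimoto_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tanimoto similarity |intersection| / |union| between binary rows.

    ``a`` is (na, L) and ``b`` is (nb, L); returns (na, nb). Two all-zero
    fingerprints are identical, so their similarity is defined as 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.int64))
    b = np.atleast_2d(np.asarray(b, dtype=np.int64))
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def build_pair_dataset(
    matrix: ResponseMatrix,
    expression: pd.DataFrame,
    drugs: DrugFeatureSet,
    sample_ids=None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Long-format (sample, drug) pairs for pan-drug models.

    Returns ``X`` (n_pairs, n_bits + n_genes) with fingerprint columns
    first, the observed responses ``y``, and a meta frame with the
    ``sample_id``/``drug_id`` of each row. Only observed cells become rows.
    """
    if sample_ids is None:
        sample_ids = matrix.sample_ids
    sub = matrix.restrict_samples(sample_ids)
    missing_expr = [s for s in sub.sample_ids if s not in set(expression.index)]
    if missing_expr:
        raise KeyError(f"no expression for samples: {missing_expr[:5]}")
    fp = drugs.matrix(sub.drug_ids)  # raises KeyError naming missing drugs
    expr = expression.loc[sub.sample_ids].to_numpy()
    vals = sub.values.to_numpy()
    rows_j, cols_i = np.nonzero(np.isfinite(vals))
    X = np.hstack([fp[cols_i], expr[rows_j]])
    y = vals[rows_j, cols_i]
    meta = pd.DataFrame(
        {
            "sample_id": np.asarray(sub.sample_ids, dtype=object)[rows_j],
            "drug_id": np.asarray(sub.drug_ids, dtype=object)[cols_i],
        }
    )
    return X, y, meta


class DrugMeanRegressor(BaseEstimator, RegressorMixin):
    """Per-drug train-set mean as the prediction for every test sample.

    The canonical drug-dominance baseline: blind to omics by construction,
    so the zero-filled ablation cannot change its output. ``X`` is the
    (n, 1) array of drug ids.
    """

    def fit(self, X, y):
        drug_ids = np.asarray(X, dtype=object).reshape(len(y))
        y = np.asarray(y, dtype=float)
        self.drug_means_ = pd.Series(y).groupby(pd.Series(drug_ids)).mean().to_dict()
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        drug_ids = np.asarray(X, dtype=object).reshape(-1)
        unknown = sorted({d for d in drug_ids if d not in self.drug_means_})
        if unknown:
            logger.warning("no train responses for drug(s) %s; predictions undefined", unknown)
        return np.array([self.drug_means_.get(d, np.nan) for d in drug_ids])


class BimodalKNNRegressor(BaseEstimator, RegressorMixin):
    """k-nearest-neighbour regression in a bimodal drug/omics space.

    The distance between two (sample, drug) pairs combines an inversed
    Tanimoto similarity of the drug fingerprints with a normalized Euclidean
    distance between expression profiles:

        d = w * (1 - Tanimoto(fp, fp')) + (1 - w) * ||e - e'|| / scale

    where ``scale`` is the largest train-set expression distance, so both
    modalities lie in [0, 1]. The prediction is the mean response of the k
    nearest train pairs. With ``zero_fill_omics`` the expression vectors are
    replaced by zeros, making the omics term constant: the ranking then
    depends on the drug alone.
    """

    def __init__(
        self,
        n_neighbors: int = 5,
        drug_weight: float = 0.5,
        n_drug_features: int | None = None,
        zero_fill_omics: bool = False,
    ):
        self.n_neighbors = n_neighbors
        self.drug_weight = drug_weight
        self.n_drug_features = n_drug_features
        self.zero_fill_omics = zero_fill_omics

    def _split(self, X):
        L = self.n_drug_features
        fp = X[:, :L]
        expr = np.zeros_like(X[:, L:]) if self.zero_fill_omics else X[:, L:]
        return fp, expr

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        if self.n_drug_features is None or not 0 < self.n_drug_features < X.shape[1]:
            raise ValueError("n_drug_features must split X into fingerprint and omics blocks")
        if self.n_neighbors < 1 or self.n_neighbors > len(y):
            raise ValueError(f"n_neighbors={self.n_neighbors} outside [1, n_train={len(y)}]")
        if not 0 <= self.drug_weight <= 1:
            raise ValueError("drug_weight must be in [0, 1]")
        fp, expr = self._split(X)
        if not np.isin(fp, (0, 1)).all():
            raise ValueError("fingerprint block must be binary")
        self.train_fp_ = fp.astype(np.int8)
        self.train_expr_ = expr
        self.train_y_ = y
        if self.zero_fill_omics:
            self.expr_scale_ = 1.0
        else:
            # largest pairwise train distance, computed blockwise
            sq = (expr**2).sum(axis=1)
            d2 = sq[:, None] + sq[None, :] - 2.0 * (expr @ expr.T)
            self.expr_scale_ = float(np.sqrt(max(d2.max(), 0.0))) or 1.0
        return self

    def _distances(self, X):
        fp, expr = self._split(X)
        d_drug = 1.0 - tanimoto_similarity(fp, self.train_fp_)
        sq_a = (expr**2).sum(axis=1)[:, None]
        sq_b = (self.train_expr_**2).sum(axis=1)[None, :]
        d2 = np.maximum(sq_a + sq_b - 2.0 * (expr @ self.train_expr_.T), 0.0)
        d_expr = np.clip(np.sqrt(d2) / self.expr_scale_, 0.0, 1.0)
        return self.drug_weight * d_drug + (1.0 - self.drug_weight) * d_expr

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        dist = self._distances(X)
        # stable argsort: ties resolved by train-row order, reproducibly
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.n_neighbors]
        return self.train_y_[order].mean(axis=1)


class FeedForwardRegressor(BaseEstimator, RegressorMixin):
    """Fully connected network on [fingerprint | expression] features.

    Three hidden layers and a linear output unit, trained with an MSE loss
    (a thin deterministic wrapper over scikit-learn's ``MLPRegressor``).
    Supports the same zero-filled-omics ablation as the kNN model.
    """

    def __init__(
        self,
        hidden_layer_sizes=(256, 128, 64),
        n_drug_features: int | None = None,
        zero_fill_omics: bool = False,
        max_iter: int = 400,
        early_stopping: bool = True,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_drug_features = n_drug_features
        self.zero_fill_omics = zero_fill_omics
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.random_state = random_state

    def _maybe_zero(self, X):
        if not self.zero_fill_omics:
            return X
        X = X.copy()
        X[:, self.n_drug_features :] = 0.0
        return X

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        if self.zero_fill_omics and self.n_drug_features is None:
            raise ValueError("zero_fill_omics requires n_drug_features")
        self.net_ = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            max_iter=self.max_iter,
            early_stopping=self.early_stopping,
            n_iter_no_change=15,
            random_state=self.random_state,
        )
        self.net_.fit(self._maybe_zero(X), y)
        if not np.isfinite(self.net_.loss_):
            raise RuntimeError(
                f"training diverged: loss={self.net_.loss_} after {self.net_.n_iter_} iterations"
            )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.net_.predict(self._maybe_zero(X))


def _registry(random_state: int = 0) -> dict:
    return {
        "ridge": Ridge(alpha=10.0),
        "knn": KNeighborsRegressor(),
        "svr_linear": SVR(kernel="linear"),
        "svr_rbf": SVR(kernel="rbf"),
        "svr_poly": SVR(kernel="poly"),
        "decision_tree": DecisionTreeRegressor(random_state=random_state),
        "random_forest": RandomForestRegressor(n_estimators=100, random_state=random_state),
        "mlp": MLPRegressor(hidden_layer_sizes=(64, 32), max_iter=500, random_state=random_state),
    }


REGISTRY_NAMES = tuple(_registry())
REGRESSOR_REGISTRY = REGISTRY_NAMES  # public alias: the available names


def make_single_drug_regressor(name: str, random_state: int = 0, **overrides):
    """Instantiate a registered single-drug regressor by name."""
    registry = _registry(random_state)
    if name not in registry:
        raise ValueError(f"unknown regressor {name!r}; available: {sorted(registry)}")
    est = registry[name]
    if overrides:
        est.set_params(**overrides)
    return est


def single_drug_fit_predict(
    train_response: pd.Series,
    expression: pd.DataFrame,
    regressor_name: str = "ridge",
    selected_genes=None,
    test_samples=None,
    random_state: int = 0,
    **overrides,
) -> pd.Series:
    """Fit one drug's regressor on selected genes, predict held-out samples."""
    if selected_genes is None or len(selected_genes) == 0:
        raise ValueError("selected_genes must be non-empty")
    train_response = pd.Series(train_response).dropna()
    if len(train_response) < 10:
        raise ValueError("need at least 10 train samples")
    if test_samples is None:
        test_samples = [s for s in expression.index if s not in set(train_response.index)]
    est = make_single_drug_regressor(regressor_name, random_state=random_state, **overrides)
    est.fit(
        expression.loc[train_response.index, list(selected_genes)].to_numpy(),
        train_response.to_numpy(),
    )
    pred = est.predict(expression.loc[list(test_samples), list(selected_genes)].to_numpy())
    return pd.Series(pred, index=list(test_samples))


def linear_model_to_json(est, gene_ids) -> dict:
    """Serializable coefficients of a fitted linear-kind regressor."""
    if not hasattr(est, "coef_"):
        raise TypeError("only linear-kind regressors expose coefficients")
    return {
        "kind": type(est).__name__,
        "intercept": float(np.ravel([est.intercept_])[0]),
        "coefficients": dict(zip(list(gene_ids), map(float, np.ravel(est.coef_)))),
    }
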
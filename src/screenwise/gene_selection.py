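"""Drug-specific gene selection.

Three stages: (1) multicollinearity removal over the expression matrix via
iterative agglomerative clustering on 1 - |Pearson r| distances; (2) five
per-gene relevance scores against one drug's responses; (3) a 100-threshold
cross-validated sweep that picks the (score, threshold) combination giving
the best held-out Pearson correlation for that drug.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import mutual_info_regression
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.svm import LinearSVR

__all__ = [
    "CorrelationPruner",
    "remove_multicollinearity",
    "relevance_scores",
    "threshold_sweep",
    "GeneSelectionResult",
    "SCORE_NAMES",
]

logger = logging.getLogger(__name__)

SCORE_NAMES = ("pearson", "spearman", "mutual_information", "poly2_ssr", "linear_svm_coef")


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r at sample size n (t distribution)."""
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Remove multicollinear genes, keeping one representative per cluster.

    Agglomerative clustering with complete linkage on 1 - |Pearson r|
    distances, cut at ``1 - r_threshold``; the highest-variance gene of each
    cluster (ties by lexicographic id) is retained and the procedure repeats
    on the representatives until every cluster is a singleton. Pairs whose
    correlation is not significant at ``p_threshold`` are never linked, so
    the retained set has no pair with |r| >= ``r_threshold`` and
    p < ``p_threshold``. Constant genes are dropped upfront.

    Attributes
    ----------
    selected_genes_ : list
        Retained gene ids, in input column order.
    cluster_map_ : dict
        representative -> list of dropped genes it stands for.
    """

    def __init__(self, r_threshold: float = 0.6, p_threshold: float = 0.05):
        self.r_threshold = r_threshold
        self.p_threshold = p_threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least 2 genes")
        if n < 3:
            raise ValueError("need at least 3 samples")
        variances = X.var(axis=0, ddof=0)
        constant = list(variances.index[variances == 0])
        if constant:
            warnings.warn(
                f"dropping {len(constant)} constant gene(s): {constant[:10]}", stacklevel=2
            )
        absorbed: dict = {g: [] for g in X.columns if g not in set(constant)}
        current = [g for g in X.columns if g not in set(constant)]

        while len(current) > 1:
            sub = X[current].to_numpy()
            r = np.corrcoef(sub, rowvar=False)
            d = 1.0 - np.abs(r)
            pvals = _corr_pvalues(r, n)
            d[pvals >= self.p_threshold] = 1.0  # insignificant: never linked
            np.fill_diagonal(d, 0.0)
            d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
            Z = linkage(squareform(d, checks=False), method="complete")
            clusters = fcluster(Z, t=1.0 - self.r_threshold, criterion="distance")
            if clusters.max() == len(current):  # all singletons: done
                break
            keep = []
            for c in np.unique(clusters):
                members = [current[i] for i in np.nonzero(clusters == c)[0]]
                rep = min(members, key=lambda g: (-variances[g], str(g)))
                keep.append(rep)
                for m in members:
                    if m != rep:
                        absorbed[rep].extend([m] + absorbed.pop(m))
            current = [g for g in current if g in set(keep)]

        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.selected_genes_ = [g for g in X.columns if g in set(current)]
        self.cluster_map_ = {g: sorted(absorbed[g]) for g in self.selected_genes_}
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[self.selected_genes_]


def remove_multicollinearity(
    expr: pd.DataFrame, r_threshold: float = 0.6, p_threshold: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Functional wrapper over :class:`CorrelationPruner`."""
    pruner = CorrelationPruner(r_threshold=r_threshold, p_threshold=p_threshold).fit(expr)
    return expr[pruner.selected_genes_], pruner.cluster_map_


def relevance_scores(
    expr: pd.DataFrame, response: pd.Series, random_state: int = 0
) -> pd.DataFrame:
    """Five per-gene relevance scores for one drug, larger = more relevant.

    Scores: |Pearson r|, |Spearman rho|, mutual information (k-nearest-
    neighbor estimator for continuous variables, k=3), negated sum of
    squared residuals of a degree-2 polynomial fit, and |coefficient| of a
    linear SVM regression fitted on all genes jointly.
    """
    response = pd.Series(response).dropna()
    samples = [s for s in expr.index if s in set(response.index)]
    if len(samples) < 10:
        raise ValueError("need at least 10 samples with observed response")
    X = expr.loc[samples].to_numpy()
    y = response.loc[samples].to_numpy()
    n, p = X.shape

    def abs_corr(M, v):
        Mc = M - M.mean(axis=0)
        vc = v - v.mean()
        denom = np.sqrt((Mc**2).sum(axis=0) * (vc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.abs(Mc.T @ vc / denom)

    pearson = abs_corr(X, y)
    ranks_X = stats.rankdata(X, axis=0)
    ranks_y = stats.rankdata(y)
    spearman = abs_corr(ranks_X, ranks_y)
    mi = mutual_info_regression(X, y, n_neighbors=3, random_state=random_state)

    if n >= 3:
        # SSR of a separate quadratic fit per gene
        poly_ssr = np.empty(p)
        for j in range(p):
            coeffs = np.polynomial.polynomial.polyfit(X[:, j], y, 2)
            resid = y - np.polynomial.polynomial.polyval(X[:, j], coeffs)
            poly_ssr[j] = (resid**2).sum()
        poly_score = -poly_ssr  # low residual = relevant
    else:
        poly_score = np.full(p, np.nan)

    svm = LinearSVR(C=1.0, random_state=random_state, max_iter=20000, tol=1e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        svm.fit(X, y)
    svm_coef = np.abs(np.ravel(svm.coef_))

    return pd.DataFrame(
        {
            "pearson": pearson,
            "spearman": spearman,
            "mutual_information": mi,
            "poly2_ssr": poly_score,
            "linear_svm_coef": svm_coef,
        },
        index=expr.columns,
    )


@dataclass
class GeneSelectionResult:
    """Best (score, threshold) combination found by the sweep for one drug."""

    drug_id: str
    score_name: str
    threshold: float
    selected_genes: list
    cv_performance: float
    sweep_table: pd.DataFrame = field(repr=False, default=None)

    def to_jsonable(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "score_name": self.score_name,
            "threshold": float(self.threshold),
            "selected_genes": list(self.selected_genes),
            "cv_performance": float(self.cv_performance),
        }


def _cv_pearson(X: np.ndarray, y: np.ndarray, folds, fold_columns, model_factory) -> float:
    """Mean held-out Pearson r between observed and predicted, over folds.

    ``fold_columns[f]`` gives the gene columns each fold may use, so gene
    selection stays inside the training fold.
    """
    rs = []
    for (train_idx, test_idx), cols in zip(folds, fold_columns):
        if len(cols) == 0:
            continue
        model = model_factory()
        model.fit(X[np.ix_(train_idx, cols)], y[train_idx])
        pred = model.predict(X[np.ix_(test_idx, cols)])
        if np.ptp(y[test_idx]) == 0 or np.ptp(pred) == 0:
            continue
        rs.append(stats.pearsonr(y[test_idx], pred).statistic)
    return float(np.mean(rs)) if rs else np.nan


def threshold_sweep(
    expr: pd.DataFrame,
    response: pd.Series,
    scores: pd.DataFrame | None = None,
    model_factory=None,
    n_thresholds: int = 100,
    cv: int = 10,
    seed: int = 0,
    score_names=SCORE_NAMES,
    drug_id: str = "",
    refit_scores_per_fold: bool = True,
) -> GeneSelectionResult:
    """Sweep 100 score thresholds per relevance score, pick the best.

    Thresholds are equally spaced quantiles of each score's empirical
    distribution, so the grid adapts to any score scale. Each candidate gene
    set is evaluated by cross-validated Pearson correlation of a single-drug
    model (ridge regression with alpha=10 by default); ties are broken
    toward fewer genes. Candidates passing zero genes are skipped.

    By default the relevance scores are recomputed inside each training fold
    (no test leakage); the reported ``selected_genes`` are then the
    full-data gene set at the winning (score, quantile). Set
    ``refit_scores_per_fold=False`` to evaluate with the full-data scores —
    the optimistic protocol some replication studies need.
    """
    if model_factory is None:
        model_factory = lambda: Ridge(alpha=10.0)
    response = pd.Series(response).dropna()
    samples = [s for s in expr.index if s in set(response.index)]
    X_all = expr.loc[samples]
    y = response.loc[samples].to_numpy()
    if scores is None:
        scores = relevance_scores(X_all, response, random_state=seed)

    if np.isscalar(cv):
        splitter = KFold(n_splits=int(cv), shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros(len(samples))))
    else:
        folds = list(cv)

    if refit_scores_per_fold:
        fold_scores = [
            relevance_scores(
                X_all.iloc[tr], pd.Series(y[tr], index=X_all.index[tr]), random_state=seed
            )
            for tr, _ in folds
        ]
    else:
        fold_scores = [scores] * len(folds)

    X_np = X_all.to_numpy()
    col_of = {g: j for j, g in enumerate(X_all.columns)}
    best = None
    sweep_rows = []
    quantile_grid = np.linspace(0.0, 1.0, n_thresholds)
    for score_name in score_names:
        if score_name not in scores.columns:
            raise KeyError(f"unknown relevance score: {score_name}")
        s = scores[score_name]
        if s.isna().all():
            continue
        thresholds = np.quantile(s.dropna().to_numpy(), quantile_grid)
        fold_thresholds = [
            np.quantile(fs[score_name].dropna().to_numpy(), quantile_grid)
            if not fs[score_name].isna().all()
            else np.full(len(quantile_grid), np.nan)
            for fs in fold_scores
        ]
        seen_counts = set()
        for qi, (q, thr) in enumerate(zip(quantile_grid, thresholds)):
            genes = list(s.index[s >= thr])
            if not genes:
                logger.info("score=%s threshold=%.4g passes zero genes; skipped", score_name, thr)
                continue
            if len(genes) in seen_counts:
                continue  # same gene set as a previous threshold
            seen_counts.add(len(genes))
            fold_columns = [
                [col_of[g] for g in fs[score_name].index[fs[score_name] >= ft[qi]]]
                for fs, ft in zip(fold_scores, fold_thresholds)
            ]
            perf = _cv_pearson(X_np, y, folds, fold_columns, model_factory)
            sweep_rows.append(
                {
                    "score": score_name,
                    "quantile": q,
                    "threshold": thr,
                    "n_genes": len(genes),
                    "cv_performance": perf,
                }
            )
            if np.isnan(perf):
                continue
            key = (perf, -len(genes))
            if best is None or key > best[0]:
                best = (key, score_name, thr, genes)
    if best is None:
        raise ValueError("no (score, threshold) candidate could be evaluated")
    _, score_name, thr, genes = best
    order = scores.loc[genes, score_name].sort_values(ascending=False)
    ordered = sorted(genes, key=lambda g: (-order[g], str(g)))
    return GeneSelectionResult(
        drug_id=drug_id,
        score_name=score_name,
        threshold=float(thr),
        selected_genes=ordered,
        cv_performance=float(best[0][0]),
        sweep_table=pd.DataFrame(sweep_rows),
    )
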
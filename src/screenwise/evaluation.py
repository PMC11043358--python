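"""Metrics, cross-validation, the four-setting experiment matrix, and
zero-shot transfer evaluation.

The experiment matrix crosses (measure: raw vs per-drug z-scored) with
(omics: real vs zero-filled) for each pan-drug model under sample-disjoint
cross-validation. Ranking metrics treat the *smallest* measure value as the
top (most sensitive) drug for every shipped measure.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DrugFeatureSet, ResponseMatrix
from .measures import harmonize_expression, zscore_by_drug
from .models import (
    BimodalKNNRegressor,
    DrugMeanRegressor,
    FeedForwardRegressor,
    build_pair_dataset,
)

__all__ = [
    "precision_at_k",
    "ndcg_at_k",
    "make_cv_folds",
    "per_sample_metrics",
    "per_drug_metrics",
    "EvaluationReport",
    "run_setting_matrix",
    "zero_shot_transfer",
]

logger = logging.getLogger(__name__)


def _rank_order(values: pd.Series, lower_is_better: bool = True) -> list:
    """Drug ids from most to least sensitive; ties broken by drug id."""
    sign = 1.0 if lower_is_better else -1.0
    return [d for d, _ in sorted(values.items(), key=lambda kv: (sign * kv[1], str(kv[0])))]


def precision_at_k(
    true_responses: pd.Series,
    predicted: pd.Series,
    k: int = 5,
    lower_is_better: bool = True,
) -> float:
    """Fraction of the true top-k most-sensitive drugs recovered in the
    predicted top-k. Ties at the k-boundary are broken by drug id after the
    value sort, so the result is deterministic. Returns NaN (with a warning)
    when fewer than k drugs are observed.
    """
    true_responses = pd.Series(true_responses).dropna()
    predicted = pd.Series(predicted).loc[true_responses.index]
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(true_responses) < k or predicted.isna().any():
        warnings.warn(f"precision@{k} undefined: fewer than k observed drugs", stacklevel=2)
        return np.nan
    top_true = set(_rank_order(true_responses, lower_is_better)[:k])
    top_pred = set(_rank_order(predicted, lower_is_better)[:k])
    return len(top_true & top_pred) / k


def _dcg(relevances: np.ndarray, k: int) -> float:
    rel = relevances[:k]
    return float((rel / np.log2(np.arange(2, len(rel) + 2))).sum())


def ndcg_at_k(
    true_responses: pd.Series,
    predicted: pd.Series,
    k: int = 5,
    lower_is_better: bool = True,
) -> float:
    """Normalized discounted cumulative gain of the predicted ranking.

    The relevance of a drug is ``(worst - value) / (worst - best)`` over the
    sample's observed responses, so the most sensitive drug has relevance 1
    and the least sensitive 0. DCG uses the log2 positional discount; the
    ideal ordering normalizes it. A perfect ranking scores 1. When all
    relevances are zero (a constant profile) the value is undefined.
    """
    true_responses = pd.Series(true_responses).dropna()
    predicted = pd.Series(predicted).loc[true_responses.index]
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(true_responses) < k or predicted.isna().any():
        warnings.warn(f"NDCG@{k} undefined: fewer than k observed drugs", stacklevel=2)
        return np.nan
    vals = true_responses.to_numpy(dtype=float)
    worst = vals.max() if lower_is_better else vals.min()
    best = vals.min() if lower_is_better else vals.max()
    if worst == best:
        warnings.warn("NDCG undefined: all relevances are zero", stacklevel=2)
        return np.nan
    rel = (worst - true_responses) / (worst - best)
    if not lower_is_better:
        rel = -rel
    pred_order = _rank_order(predicted, lower_is_better)
    dcg = _dcg(rel.loc[pred_order].to_numpy(), k)
    idcg = _dcg(np.sort(rel.to_numpy())[::-1], k)
    return dcg / idcg


def make_cv_folds(sample_ids, n_folds: int, seed: int = 0) -> pd.Series:
    """Sample-disjoint fold assignment, sizes differing by at most one."""
    sample_ids = list(sample_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(sample_ids):
        raise ValueError(f"n_folds={n_folds} exceeds {len(sample_ids)} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sample_ids))
    assignment = np.empty(len(sample_ids), dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        assignment[chunk] = fold
    return pd.Series(assignment, index=sample_ids, name="fold")


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN (undefined) for constant inputs — never 0 or 1."""
    if len(a) < 2:
        return np.nan
    # near-zero spread (e.g. a mean baseline fed exactly-centered z-scores)
    # is a degenerate constant predictor, not a correlation of 0 or 1
    tol = 1e-12
    if np.ptp(a) <= tol * max(1.0, np.abs(a).max()) or np.ptp(b) <= tol * max(1.0, np.abs(b).max()):
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def _grouped_metrics(obs: pd.Series, pred: pd.Series, meta: pd.DataFrame, by: str) -> pd.DataFrame:
    rows = []
    for key, idx in meta.groupby(by).groups.items():
        o = obs.loc[idx].to_numpy()
        p = pred.loc[idx].to_numpy()
        rows.append(
            {
                by: key,
                "pearson": _safe_pearson(o, p),
                "mse": float(np.mean((o - p) ** 2)),
                "n": len(idx),
            }
        )
    return pd.DataFrame(rows).set_index(by)


def per_sample_metrics(obs, pred, meta) -> pd.DataFrame:
    """Pearson and MSE of predictions per sample (across its drugs)."""
    return _grouped_metrics(obs, pred, meta, "sample_id")


def per_drug_metrics(obs, pred, meta) -> pd.DataFrame:
    """Pearson and MSE of predictions per drug (across samples)."""
    return _grouped_metrics(obs, pred, meta, "drug_id")


@dataclass
class EvaluationReport:
    """Long-format metric table: one row per (model, measure, omics, fold, metric)."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of each metric across folds."""
        g = self.table.groupby(["model", "measure", "omics", "metric"])["value"]
        out = g.agg(["mean", "std", "count"])
        return out.reset_index()

    def value(self, model, measure, omics, metric, agg="mean") -> float:
        t = self.table
        sel = t[
            (t["model"] == model)
            & (t["measure"] == measure)
            & (t["omics"] == omics)
            & (t["metric"] == metric)
        ]["value"]
        return float(sel.mean()) if agg == "mean" else sel

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_jsonable(self) -> dict:
        return {"meta": self.meta, "rows": self.table.to_dict(orient="records")}


def _default_models(drugs: DrugFeatureSet, seed: int) -> dict:
    L = drugs.n_bits

    def factory(name, zero_fill):
        if name == "mean":
            return DrugMeanRegressor()
        if name == "knn":
            return BimodalKNNRegressor(n_drug_features=L, zero_fill_omics=zero_fill)
        if name == "feedforward":
            return FeedForwardRegressor(
                n_drug_features=L, zero_fill_omics=zero_fill, random_state=seed
            )
        raise ValueError(f"unknown model {name!r}")

    return factory


def _fit_predict_cell(
    model_name, factory, zero_fill, matrix, expression, drugs, train_samples, test_samples
):
    """Fit one model on the train split, predict the observed test cells."""
    if model_name == "mean":
        _, y_tr, meta_tr = build_pair_dataset(matrix, expression, drugs, train_samples)
        _, y_te, meta_te = build_pair_dataset(matrix, expression, drugs, test_samples)
        est = factory(model_name, zero_fill).fit(meta_tr[["drug_id"]].to_numpy(), y_tr)
        pred = est.predict(meta_te[["drug_id"]].to_numpy())
    else:
        X_tr, y_tr, _ = build_pair_dataset(matrix, expression, drugs, train_samples)
        X_te, y_te, meta_te = build_pair_dataset(matrix, expression, drugs, test_samples)
        est = factory(model_name, zero_fill).fit(X_tr, y_tr)
        pred = est.predict(X_te)
    return pd.Series(y_te), pd.Series(pred), meta_te


def _cell_metric_rows(obs, pred, meta, k, model, measure_label, omics, fold) -> list:
    ok = pred.notna()
    obs, pred, meta = obs[ok], pred[ok], meta[ok]
    ps = per_sample_metrics(obs, pred, meta)
    pdm = per_drug_metrics(obs, pred, meta)
    prec, ndcg = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined samples are just skipped
        for sid, idx in meta.groupby("sample_id").groups.items():
            t, p = obs.loc[idx], pred.loc[idx]
            t.index = p.index = meta.loc[idx, "drug_id"]
            prec.append(precision_at_k(t, p, k))
            ndcg.append(ndcg_at_k(t, p, k))
    base = {"model": model, "measure": measure_label, "omics": omics, "fold": fold}
    return [
        {**base, "metric": "per_sample_pearson", "value": float(ps["pearson"].mean())},
        {**base, "metric": "per_sample_mse", "value": float(ps["mse"].mean())},
        {**base, "metric": "per_drug_pearson", "value": float(pdm["pearson"].mean())},
        {**base, "metric": "per_drug_mse", "value": float(pdm["mse"].mean())},
        {**base, "metric": f"precision_at_{k}", "value": float(np.nanmean(prec)) if prec else np.nan},
        {**base, "metric": f"ndcg_at_{k}", "value": float(np.nanmean(ndcg)) if ndcg else np.nan},
    ]


def run_setting_matrix(
    matrix: ResponseMatrix,
    expression: pd.DataFrame,
    drugs: DrugFeatureSet,
    models=("mean", "knn"),
    measures=("raw", "zscored"),
    omics_modes=("real", "zero_filled"),
    n_folds: int = 5,
    k: int = 5,
    seed: int = 0,
    model_factory=None,
) -> EvaluationReport:
    """Run every (model x measure x omics) cell under sample-disjoint CV.

    Z-scoring is applied to the full matrix before splitting (the z-score is
    treated as a property of the dataset). The mean baseline ignores omics,
    so its real and zero-filled cells are computed once and reported
    identically — bit-exact. A model failing on one fold marks that cell
    failed without affecting the others.
    """
    factory = model_factory or _default_models(drugs, seed)
    folds = make_cv_folds(matrix.sample_ids, n_folds, seed)
    matrices = {}
    for measure_label in measures:
        if measure_label == "raw":
            matrices[measure_label] = matrix
        elif measure_label == "zscored":
            matrices[measure_label] = zscore_by_drug(matrix)
        else:
            raise ValueError(f"unknown measure setting {measure_label!r}")

    rows = []
    failed = []
    for measure_label, mat in matrices.items():
        for fold in range(n_folds):
            train_samples = list(folds.index[folds != fold])
            test_samples = list(folds.index[folds == fold])
            for model in models:
                cached_mean = None
                for omics in omics_modes:
                    try:
                        if model == "mean" and cached_mean is not None:
                            obs, pred, meta = cached_mean
                        else:
                            obs, pred, meta = _fit_predict_cell(
                                model,
                                factory,
                                omics == "zero_filled",
                                mat,
                                expression,
                                drugs,
                                train_samples,
                                test_samples,
                            )
                            if model == "mean":
                                cached_mean = (obs, pred, meta)
                        rows.extend(
                            _cell_metric_rows(obs, pred, meta, k, model, measure_label, omics, fold)
                        )
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        logger.error(
                            "cell failed: model=%s measure=%s omics=%s fold=%d: %s",
                            model, measure_label, omics, fold, exc,
                        )
                        failed.append((model, measure_label, omics, fold, str(exc)))
    report = EvaluationReport(
        pd.DataFrame(rows),
        meta={
            "n_folds": n_folds,
            "k": k,
            "seed": seed,
            "measure": matrix.measure.name,
            "failed_cells": failed,
        },
    )
    return report


def zero_shot_transfer(
    train_bundle: dict,
    test_bundle: dict,
    models=("mean", "knn"),
    measures=("raw", "zscored"),
    omics_modes=("real", "zero_filled"),
    k: int = 5,
    seed: int = 0,
    model_factory=None,
) -> EvaluationReport:
    """Train on one screen, evaluate on another without re-training.

    Bundles are dicts with keys ``response`` (:class:`ResponseMatrix`),
    ``expression`` and ``drugs``. Expression is harmonized by the double
    z-score scheme; evaluation is restricted to the drugs shared between the
    two screens (z-scoring, when requested, is done within each dataset
    separately). No test information enters training.
    """
    train_rm, test_rm = train_bundle["response"], test_bundle["response"]
    shared_drugs = [d for d in train_rm.drug_ids if d in set(test_rm.drug_ids)]
    if not shared_drugs:
        raise ValueError("no shared drugs between train and test bundles")
    drugs = train_bundle["drugs"]
    same_samples = list(train_rm.sample_ids) == list(test_rm.sample_ids)
    if same_samples:  # degenerate self-transfer: skip cross-dataset scaling
        expr_train = train_bundle["expression"]
        expr_test = test_bundle["expression"]
    else:
        merged, origin = harmonize_expression(
            train_bundle["expression"], test_bundle["expression"]
        )
        expr_train = merged.loc[origin == "train"]
        expr_test = merged.loc[origin == "test"]

    expression = expr_train if same_samples else pd.concat([expr_train, expr_test])
    factory = model_factory or _default_models(drugs, seed)
    rows, failed = [], []
    for measure_label in measures:
        if measure_label == "raw":
            tr, te = train_rm, test_rm.restrict_drugs(shared_drugs)
        else:
            tr, te = zscore_by_drug(train_rm), zscore_by_drug(test_rm)
            te = te.restrict_drugs([d for d in shared_drugs if d in set(te.drug_ids)])
        for model in models:
            cached_mean = None
            for omics in omics_modes:
                try:
                    if model == "mean" and cached_mean is not None:
                        obs, pred, meta = cached_mean
                    else:
                        obs, pred, meta = _fit_predict_cell(
                            model,
                            factory,
                            omics == "zero_filled",
                            # train on the full train screen, predict test cells
                            _stack_for_transfer(tr, te),
                            expression,
                            drugs,
                            tr.sample_ids,
                            te.sample_ids,
                        )
                        if model == "mean":
                            cached_mean = (obs, pred, meta)
                    rows.extend(
                        _cell_metric_rows(obs, pred, meta, k, model, measure_label, omics, "transfer")
                    )
                except Exception as exc:  # noqa: BLE001
                    logger.error("transfer cell failed: %s/%s/%s: %s", model, measure_label, omics, exc)
                    failed.append((model, measure_label, omics, str(exc)))
    return EvaluationReport(
        pd.DataFrame(rows),
        meta={"transfer": True, "shared_drugs": shared_drugs, "k": k, "failed_cells": failed},
    )


def _stack_for_transfer(train_rm: ResponseMatrix, test_rm: ResponseMatrix) -> ResponseMatrix:
    """One matrix holding train rows and test rows (disjoint sample ids)."""
    overlap = set(train_rm.sample_ids) & set(test_rm.sample_ids)
    if overlap and list(train_rm.sample_ids) != list(test_rm.sample_ids):
        raise ValueError(f"sample ids overlap between bundles: {sorted(overlap)[:5]}")
    if overlap:  # degenerate self-transfer
        return train_rm
    values = pd.concat([train_rm.values, test_rm.values.reindex(columns=train_rm.drug_ids)])
    return ResponseMatrix(values, train_rm.measure)
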
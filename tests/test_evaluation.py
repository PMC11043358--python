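"""Ranking metrics, CV folds, the setting matrix, zero-shot transfer."""
import warnings

import numpy as np
import pandas as pd
import pytest

import screenwise as sw
from screenwise.evaluation import (
    make_cv_folds,
    ndcg_at_k,
    per_drug_metrics,
    precision_at_k,
    run_setting_matrix,
    zero_shot_transfer,
)


def series(values, prefix="d"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


# ---------------------------------------------------------------- metrics
def test_precision_at_k_basic_cases():
    truth = series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    assert precision_at_k(truth, truth, k=3) == 1.0
    reversed_pred = series([0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
    assert precision_at_k(truth, reversed_pred, k=3) == 0.0
    # exactly two of the true top-3 in the predicted top-3
    pred = series([0.1, 0.2, 9.0, 0.3, 8.0, 7.0])
    assert precision_at_k(truth, pred, k=3) == pytest.approx(2 / 3)


def test_precision_at_k_undefined_when_too_few_drugs():
    truth = series([0.1, 0.2])
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(precision_at_k(truth, truth, k=5))


def test_ndcg_perfect_and_reversed_rankings():
    truth = series([0.0, 1.0, 2.0, 3.0])
    assert ndcg_at_k(truth, truth, k=4) == pytest.approx(1.0)
    assert ndcg_at_k(truth, -truth, k=3) < 1.0


def test_ndcg_hand_computed_swap_of_top_two():
    # relevances (1, 2/3, 1/3, 0); prediction swaps the top two items
    truth = series([0.0, 1.0, 2.0, 3.0])
    pred = series([1.0, 0.0, 2.0, 3.0])
    rel = np.array([1.0, 2 / 3, 1 / 3, 0.0])
    discount = 1.0 / np.log2(np.arange(2, 6))
    dcg = (rel[[1, 0, 2, 3]] * discount).sum()
    idcg = (rel * discount).sum()
    assert ndcg_at_k(truth, pred, k=4) == pytest.approx(dcg / idcg, abs=1e-12)


def test_ndcg_undefined_on_constant_profile():
    truth = series([1.0, 1.0, 1.0])
    with pytest.warns(UserWarning, match="relevances"):
        assert np.isnan(ndcg_at_k(truth, series([1.0, 2.0, 3.0]), k=3))


def brute_precision(truth, pred, k):
    top_t = sorted(truth.index, key=lambda d: (truth[d], d))[:k]
    top_p = sorted(pred.index, key=lambda d: (pred[d], d))[:k]
    return len(set(top_t) & set(top_p)) / k


def brute_ndcg(truth, pred, k):
    worst, best = truth.max(), truth.min()
    rel = {d: (worst - truth[d]) / (worst - best) for d in truth.index}
    order_p = sorted(pred.index, key=lambda d: (pred[d], d))
    order_t = sorted(truth.index, key=lambda d: (truth[d], d))
    dcg = sum(rel[d] / np.log2(i + 2) for i, d in enumerate(order_p[:k]))
    idcg = sum(rel[d] / np.log2(i + 2) for i, d in enumerate(order_t[:k]))
    return dcg / idcg


def test_metrics_match_brute_force_over_random_instances():
    """1000 random instances (with ties), exact agreement with the oracles."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(2, 13))
        k = int(rng.integers(1, n + 1))
        truth = series(np.round(rng.normal(size=n), 1))  # rounding makes ties
        pred = series(np.round(rng.normal(size=n), 1))
        if truth.max() == truth.min():
            continue
        assert precision_at_k(truth, pred, k) == brute_precision(truth, pred, k)
        assert ndcg_at_k(truth, pred, k) == pytest.approx(
            brute_ndcg(truth, pred, k), abs=1e-12
        )


# ---------------------------------------------------------------- CV folds
def test_cv_folds_partition_the_samples():
    ids = [f"s{i}" for i in range(10)]
    folds = make_cv_folds(ids, 5, seed=1)
    assert sorted(folds.index) == sorted(ids)
    assert folds.value_counts().tolist() == [2, 2, 2, 2, 2]
    pd.testing.assert_series_equal(folds, make_cv_folds(ids, 5, seed=1))
    assert not folds.equals(make_cv_folds(ids, 5, seed=2))
    with pytest.raises(ValueError, match="exceeds"):
        make_cv_folds(ids, 11)


def test_cv_fold_sizes_differ_by_at_most_one():
    folds = make_cv_folds([f"s{i}" for i in range(13)], 5, seed=0)
    counts = folds.value_counts()
    assert counts.max() - counts.min() <= 1


# ------------------------------------------------------ setting matrix
@pytest.fixture(scope="module")
def small_matrix_run(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_setting_matrix(
            m, small_bundle.expression, small_bundle.drug_features,
            models=("mean", "knn"), n_folds=4, seed=0,
        )
    return report


def test_setting_matrix_has_all_cells(small_matrix_run):
    t = small_matrix_run.table
    cells = t.groupby(["model", "measure", "omics"]).ngroups
    assert cells == 8  # 2 models x 2 measures x 2 omics modes
    assert set(t["fold"]) == {0, 1, 2, 3}
    assert small_matrix_run.meta["failed_cells"] == []


def test_mean_baseline_identical_across_omics_modes(small_matrix_run):
    t = small_matrix_run.table
    real = t[(t.model == "mean") & (t.omics == "real")].set_index(["measure", "fold", "metric"])
    zero = t[(t.model == "mean") & (t.omics == "zero_filled")].set_index(
        ["measure", "fold", "metric"]
    )
    pd.testing.assert_series_equal(real["value"], zero["value"])  # bit-exact


def test_aggregate_means_lie_within_fold_range(small_matrix_run):
    t = small_matrix_run.table
    agg = small_matrix_run.aggregate()
    for _, row in agg.iterrows():
        vals = t[
            (t.model == row["model"]) & (t.measure == row["measure"])
            & (t.omics == row["omics"]) & (t.metric == row["metric"])
        ]["value"].dropna()
        if vals.empty or np.isnan(row["mean"]):
            continue
        assert vals.min() - 1e-12 <= row["mean"] <= vals.max() + 1e-12


def test_constant_predictor_per_drug_pearson_is_undefined():
    obs = pd.Series([1.0, 2.0, 3.0, 4.0])
    pred = pd.Series([2.5, 2.5, 2.5, 2.5])  # a drug-mean prediction
    meta = pd.DataFrame({"sample_id": list("abcd"), "drug_id": ["dX"] * 4})
    out = per_drug_metrics(obs, pred, meta)
    assert np.isnan(out.loc["dX", "pearson"])  # undefined, never 0 or 1


# ------------------------------------------------------ zero-shot transfer
def test_degenerate_self_transfer_equals_training_set_evaluation(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    bundle = {
        "response": m, "expression": small_bundle.expression,
        "drugs": small_bundle.drug_features,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = zero_shot_transfer(bundle, bundle, models=("mean",), measures=("raw",))
    v = rep.value("mean", "raw", "real", "per_sample_pearson")
    # oracle: per-sample correlation of drug means with the full matrix
    means = m.values.mean(axis=0)
    oracle = m.values.apply(lambda row: row.corr(means), axis=1).mean()
    assert v == pytest.approx(oracle, abs=1e-12)


def test_transfer_rejects_disjoint_drug_panels(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    renamed = m.values.copy()
    renamed.columns = [f"other_{d}" for d in renamed.columns]
    other = {
        "response": sw.ResponseMatrix(renamed, sw.LN_IC50),
        "expression": small_bundle.expression,
        "drugs": small_bundle.drug_features,
    }
    mine = {
        "response": m, "expression": small_bundle.expression,
        "drugs": small_bundle.drug_features,
    }
    with pytest.raises(ValueError, match="no shared drugs"):
        zero_shot_transfer(mine, other)
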
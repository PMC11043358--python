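"""Prediction models: mean baseline, bimodal kNN, feed-forward, registry."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import screenwise as sw
from screenwise.models import (
    BimodalKNNRegressor,
    DrugMeanRegressor,
    FeedForwardRegressor,
    build_pair_dataset,
    make_single_drug_regressor,
    single_drug_fit_predict,
    tanimoto_similarity,
)


def test_tanimoto_reference_values():
    a = np.zeros(8); a[[1, 2, 3]] = 1
    b = np.zeros(8); b[[2, 3, 4]] = 1
    assert tanimoto_similarity(a, a)[0, 0] == 1.0
    assert tanimoto_similarity(a, 1 - a)[0, 0] == 0.0
    assert tanimoto_similarity(a, b)[0, 0] == 0.5  # |{2,3}| / |{1,2,3,4}|
    assert tanimoto_similarity(np.zeros(8), np.zeros(8))[0, 0] == 1.0


def test_mean_baseline_predicts_train_drug_means():
    est = DrugMeanRegressor().fit(np.array([["A"], ["A"], ["B"]]), [2.0, 4.0, 7.0])
    pred = est.predict(np.array([["A"], ["B"], ["A"]]))
    np.testing.assert_allclose(pred, [3.0, 7.0, 3.0])
    unseen = est.predict(np.array([["C"]]))
    assert np.isnan(unseen[0])  # undefined, never silently imputed


def test_knn_returns_exact_match_at_k_one(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    X, y, _ = build_pair_dataset(m, small_bundle.expression, small_bundle.drug_features)
    est = BimodalKNNRegressor(
        n_neighbors=1, n_drug_features=small_bundle.drug_features.n_bits
    ).fit(X, y)
    np.testing.assert_allclose(est.predict(X[:10]), y[:10])


def test_knn_zero_filled_gives_identical_predictions_per_drug(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    X, y, meta = build_pair_dataset(m, small_bundle.expression, small_bundle.drug_features)
    train = meta["sample_id"].isin(m.sample_ids[:12]).to_numpy()
    est = BimodalKNNRegressor(
        n_neighbors=3, n_drug_features=small_bundle.drug_features.n_bits, zero_fill_omics=True
    ).fit(X[train], y[train])
    pred = pd.Series(est.predict(X[~train]), index=meta.loc[~train, "drug_id"].to_numpy())
    assert (pred.groupby(level=0).nunique() == 1).all()


def test_knn_matches_brute_force_on_small_instances():
    rng = np.random.default_rng(0)
    L, G, n_train, n_test, w = 16, 5, 18, 7, 0.5
    fp = rng.integers(0, 2, (n_train + n_test, L)).astype(float)
    expr = rng.normal(size=(n_train + n_test, G))
    X = np.hstack([fp, expr])
    y = rng.normal(size=n_train)
    for k in (1, 3, 5):
        est = BimodalKNNRegressor(n_neighbors=k, n_drug_features=L).fit(X[:n_train], y)
        pred = est.predict(X[n_train:])
        # brute force: textbook loop over all train pairs
        sq = ((expr[:n_train, None, :] - expr[:n_train][None]) ** 2).sum(-1)
        scale = np.sqrt(sq.max())
        for t in range(n_test):
            d = []
            for j in range(n_train):
                inter = (fp[n_train + t] * fp[j]).sum()
                union = fp[n_train + t].sum() + fp[j].sum() - inter
                tan = inter / union if union else 1.0
                de = min(np.linalg.norm(expr[n_train + t] - expr[j]) / scale, 1.0)
                d.append(w * (1 - tan) + (1 - w) * de)
            expected = y[np.argsort(np.asarray(d), kind="stable")[:k]].mean()
            assert pred[t] == pytest.approx(expected, abs=1e-12)


def test_knn_validates_inputs(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    X, y, _ = build_pair_dataset(m, small_bundle.expression, small_bundle.drug_features)
    with pytest.raises(ValueError, match="n_neighbors"):
        BimodalKNNRegressor(n_neighbors=len(y) + 1,
                            n_drug_features=small_bundle.drug_features.n_bits).fit(X, y)
    with pytest.raises(ValueError, match="n_drug_features"):
        BimodalKNNRegressor(n_neighbors=1).fit(X, y)


def test_pair_dataset_rejects_missing_fingerprint(small_bundle):
    m = sw.ResponseMatrix(small_bundle.truth.true_log_ic50, sw.LN_IC50)
    drugs = sw.DrugFeatureSet(small_bundle.drug_features.fingerprints.iloc[:-1])
    with pytest.raises(KeyError, match=m.drug_ids[-1]):
        build_pair_dataset(m, small_bundle.expression, drugs)


def test_single_drug_ridge_solves_a_linear_response():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.normal(size=(60, 6)),
                        index=[f"s{i}" for i in range(60)],
                        columns=[f"g{j}" for j in range(6)])
    y = 2.0 * expr["g0"] - expr["g3"] + 0.5 * expr["g5"]
    train = y.iloc[:40]
    pred = single_drug_fit_predict(train, expr, "ridge", ["g0", "g3", "g5"], alpha=1e-6)
    r = stats.pearsonr(y.loc[pred.index], pred).statistic
    assert r >= 0.999


def test_single_drug_null_response_centers_on_zero():
    rs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.normal(size=(60, 10)),
                            index=[f"s{i}" for i in range(60)],
                            columns=[f"g{j}" for j in range(10)])
        y = pd.Series(rng.normal(size=60), index=expr.index)
        pred = single_drug_fit_predict(y.iloc[:45], expr, "ridge", list(expr.columns))
        rs.append(stats.pearsonr(y.loc[pred.index], pred).statistic)
    assert abs(np.mean(rs)) <= 0.1


def test_registry_exposes_all_names_and_rejects_unknown():
    for name in ("ridge", "knn", "svr_linear", "svr_rbf", "svr_poly",
                 "decision_tree", "random_forest", "mlp"):
        est = make_single_drug_regressor(name)
        assert hasattr(est, "fit") and hasattr(est, "predict")
    assert make_single_drug_regressor("ridge").alpha == 10.0
    with pytest.raises(ValueError, match="unknown regressor"):
        make_single_drug_regressor("gradient_descent_by_hand")


def _feedforward_setup(seed=0):
    cfg = sw.SyntheticScreenConfig(
        n_samples=60, n_drugs=15, n_genes=40, coverage_fraction=1.0, seed=seed
    )
    b = sw.generate_screen(cfg)
    m = sw.ResponseMatrix(b.truth.true_log_ic50, sw.LN_IC50)
    X, y, meta = build_pair_dataset(m, b.expression, b.drug_features)
    split = meta["sample_id"].isin(m.sample_ids[:45]).to_numpy()
    return b, X, y, split


def test_feedforward_is_deterministic_and_learns_raw_responses():
    b, X, y, train = _feedforward_setup()
    L = b.drug_features.n_bits
    est = FeedForwardRegressor(n_drug_features=L, random_state=7).fit(X[train], y[train])
    pred = est.predict(X[~train])
    est2 = FeedForwardRegressor(n_drug_features=L, random_state=7).fit(X[train], y[train])
    np.testing.assert_array_equal(pred, est2.predict(X[~train]))  # bit-identical
    assert stats.pearsonr(y[~train], pred).statistic >= 0.8


def test_feedforward_zero_filled_omics_matches_real_on_drug_dominated_screen():
    b, X, y, train = _feedforward_setup(seed=3)
    L = b.drug_features.n_bits
    rs = {}
    for zero_fill in (False, True):
        est = FeedForwardRegressor(
            n_drug_features=L, zero_fill_omics=zero_fill, random_state=11
        ).fit(X[train], y[train])
        rs[zero_fill] = stats.pearsonr(y[~train], est.predict(X[~train])).statistic
    assert abs(rs[True] - rs[False]) <= 0.05
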
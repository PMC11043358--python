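"""Multicollinearity pruning, relevance scores, and the threshold sweep."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import screenwise as sw
from screenwise.gene_selection import (
    CorrelationPruner,
    relevance_scores,
    remove_multicollinearity,
    threshold_sweep,
)


def frame(arr, prefix="g"):
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j:04d}" for j in range(arr.shape[1])],
    )


def violating_pairs(expr, r_threshold=0.6, p_threshold=0.05):
    """Exhaustive oracle scan for retained pairs breaking the contract."""
    X = expr.to_numpy()
    n = len(X)
    bad = []
    for a in range(X.shape[1]):
        for b in range(a + 1, X.shape[1]):
            r, p = stats.pearsonr(X[:, a], X[:, b])
            if abs(r) >= r_threshold and p < p_threshold:
                bad.append((expr.columns[a], expr.columns[b], r))
    return bad


def test_exact_duplicates_collapse_to_one_representative():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(40, 1))
    expr = frame(np.hstack([base, base, base, rng.normal(size=(40, 3))]))
    reduced, cluster_map = remove_multicollinearity(expr)
    dup_group = {"g0000", "g0001", "g0002"}
    survivors = dup_group & set(reduced.columns)
    assert len(survivors) == 1
    rep = survivors.pop()
    assert set(cluster_map[rep]) == dup_group - {rep}


def test_independent_genes_are_mostly_retained():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        expr = frame(rng.normal(size=(200, 200)))
        reduced, _ = remove_multicollinearity(expr)
        assert reduced.shape[1] >= 0.95 * 200


def test_no_retained_pair_violates_the_correlation_contract():
    rng = np.random.default_rng(1)
    n = 60
    blocks = []
    for _ in range(10):  # correlated blocks of 5 genes each
        latent = rng.normal(size=(n, 1))
        blocks.append(0.9 * latent + 0.2 * rng.normal(size=(n, 5)))
    expr = frame(np.hstack(blocks + [rng.normal(size=(n, 30))]))
    reduced, _ = remove_multicollinearity(expr)
    assert reduced.shape[1] < expr.shape[1]
    assert violating_pairs(reduced) == []


def test_constant_genes_dropped_with_warning():
    rng = np.random.default_rng(2)
    expr = frame(rng.normal(size=(30, 4)))
    expr["g0001"] = 3.14
    with pytest.warns(UserWarning, match="constant"):
        pruner = CorrelationPruner().fit(expr)
    assert "g0001" not in pruner.selected_genes_
    assert pruner.transform(expr).shape[1] == len(pruner.selected_genes_)


def test_retained_count_monotone_in_r_threshold():
    rng = np.random.default_rng(3)
    latent = rng.normal(size=(50, 8))
    expr = frame(latent[:, np.repeat(np.arange(8), 5)] + 0.7 * rng.normal(size=(50, 40)))
    sizes = [
        remove_multicollinearity(expr, r_threshold=t)[0].shape[1] for t in (0.4, 0.6, 0.8)
    ]
    assert sizes[0] <= sizes[1] <= sizes[2]


def test_relevance_scores_rank_a_perfect_gene_on_top():
    rng = np.random.default_rng(4)
    expr = frame(rng.normal(size=(50, 10)))
    response = pd.Series(expr["g0003"].to_numpy(), index=expr.index)
    scores = relevance_scores(expr, response)
    assert scores.loc["g0003", "pearson"] == pytest.approx(1.0)
    assert scores.loc["g0003", "poly2_ssr"] == pytest.approx(0.0, abs=1e-12)
    for name in scores.columns:
        assert scores[name].idxmax() == "g0003", name


def test_independent_gene_has_small_absolute_correlation():
    rng = np.random.default_rng(5)
    expr = frame(rng.normal(size=(500, 20)))
    response = pd.Series(rng.normal(size=500), index=expr.index)
    scores = relevance_scores(expr, response)
    assert scores["pearson"].max() <= 0.15  # null |r| at n=500


def test_quadratic_signal_found_by_poly2_but_not_pearson():
    rng = np.random.default_rng(6)
    x = rng.normal(size=300)
    expr = frame(np.column_stack([x, rng.normal(size=(300, 8))]))
    response = pd.Series((x - x.mean()) ** 2, index=expr.index)  # symmetric: r ~ 0
    scores = relevance_scores(expr, response)
    assert scores["poly2_ssr"].idxmax() == "g0000"
    assert scores.loc["g0000", "pearson"] < 0.3


def test_relevance_scores_require_ten_samples():
    rng = np.random.default_rng(7)
    expr = frame(rng.normal(size=(8, 5)))
    with pytest.raises(ValueError, match="10 samples"):
        relevance_scores(expr, pd.Series(rng.normal(size=8), index=expr.index))


def test_degenerate_single_threshold_selects_all_genes():
    rng = np.random.default_rng(8)
    expr = frame(rng.normal(size=(40, 12)))
    y = pd.Series(expr["g0000"] + 0.1 * rng.normal(size=40), index=expr.index)
    res = threshold_sweep(expr, y, n_thresholds=1, cv=4, score_names=("pearson",))
    assert len(res.selected_genes) == 12


def test_sweep_invariant_to_gene_column_order():
    rng = np.random.default_rng(9)
    expr = frame(rng.normal(size=(60, 20)))
    y = pd.Series(
        expr["g0002"] - 0.8 * expr["g0011"] + 0.3 * rng.normal(size=60), index=expr.index
    )
    res1 = threshold_sweep(expr, y, cv=5, n_thresholds=20, score_names=("pearson", "spearman"))
    shuffled = expr[list(rng.permutation(expr.columns))]
    res2 = threshold_sweep(shuffled, y, cv=5, n_thresholds=20, score_names=("pearson", "spearman"))
    assert res1.score_name == res2.score_name
    assert set(res1.selected_genes) == set(res2.selected_genes)
    assert res1.cv_performance == pytest.approx(res2.cv_performance, abs=1e-12)


def test_planted_signal_sweep_recovers_causal_genes():
    """Scaled-down planted-signal screen, full-data-score (replication)
    protocol: high CV Pearson and high causal recall."""
    recalls, perfs = [], []
    for seed in (0, 1, 2):
        cfg = sw.SyntheticScreenConfig(
            n_samples=120, n_drugs=2, n_genes=300, causal_genes_per_drug=10,
            genetic_effect_sd=0.5, coverage_fraction=1.0, seed=seed,
        )
        b = sw.generate_screen(cfg)
        drug = "D000"
        z = (b.truth.true_log_ic50[drug] - b.truth.true_log_ic50[drug].mean())
        z = z / z.std(ddof=0)
        res = threshold_sweep(
            b.expression, z, cv=5, seed=seed,
            score_names=("pearson", "linear_svm_coef"), refit_scores_per_fold=False,
        )
        causal = set(b.truth.causal_gene_ids[drug])
        recalls.append(len(causal & set(res.selected_genes)) / len(causal))
        perfs.append(res.cv_performance)
    assert min(perfs) >= 0.85
    assert np.mean(recalls) >= 0.8


def test_pure_noise_response_yields_no_illusory_signal():
    """With fold-internal score computation (the default), a pure-noise
    response cannot manufacture cross-validated performance."""
    rng = np.random.default_rng(12)
    expr = frame(rng.normal(size=(200, 100)))
    y = pd.Series(rng.normal(size=200), index=expr.index)
    res = threshold_sweep(expr, y, cv=10, seed=12, score_names=("pearson", "spearman"))
    assert res.cv_performance <= 0.2


def test_full_data_score_protocol_is_optimistic_on_noise():
    """Computing relevance scores on all samples leaks the test folds into
    selection; the same null data then shows inflated CV performance."""
    rng = np.random.default_rng(13)
    expr = frame(rng.normal(size=(150, 120)))
    y = pd.Series(rng.normal(size=150), index=expr.index)
    honest = threshold_sweep(expr, y, cv=5, seed=13, score_names=("pearson",))
    leaky = threshold_sweep(
        expr, y, cv=5, seed=13, score_names=("pearson",), refit_scores_per_fold=False
    )
    assert leaky.cv_performance > honest.cv_performance
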
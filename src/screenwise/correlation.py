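"""Pairwise correlation of drug-response profiles between samples.

The diagnostic at the heart of the package: for every unordered pair of
samples, correlate their response profiles over the drugs screened in both.
On absolute measures (ln-IC50, AUC) these correlations are very high for
essentially every pair — drug response is dominated by the drug, not the
sample — while after per-drug z-scoring they collapse to around zero.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ResponseMatrix, SubtypeAnnotation

__all__ = [
    "CorrelationReport",
    "pairwise_profile_correlation",
    "stratify_correlations",
    "pathway_restricted_correlation",
]

#: pairs sharing fewer drugs than this are reported undefined — a
#: correlation over a tiny overlap is noise
MIN_SHARED = 10


def _summary(values: pd.Series) -> dict:
    v = values.dropna()
    if v.empty:
        return {"n_pairs": 0, "median": np.nan, "q1": np.nan, "q3": np.nan, "mean": np.nan}
    return {
        "n_pairs": int(len(v)),
        "median": float(v.median()),
        "q1": float(v.quantile(0.25)),
        "q3": float(v.quantile(0.75)),
        "mean": float(v.mean()),
    }


@dataclass
class CorrelationReport:
    """Per-pair correlations (canonical order j < k) plus summaries."""

    pairs: pd.DataFrame  # sample_j, sample_k, n_shared, pearson, spearman, reason
    method: str = "pearson"
    measure_name: str = ""
    min_shared: int = MIN_SHARED
    strata: dict = field(default_factory=dict)

    def defined(self) -> pd.DataFrame:
        return self.pairs[self.pairs[self.method].notna()]

    def summary(self, method: str | None = None) -> dict:
        return _summary(self.pairs[method or self.method])

    def to_tsv(self, path) -> None:
        cols = ["sample_j", "sample_k", "n_shared", "pearson", "spearman"]
        self.pairs[cols].to_csv(path, sep="\t", index=False)


def pairwise_profile_correlation(
    matrix: ResponseMatrix,
    method: str = "pearson",
    min_shared: int = MIN_SHARED,
    subsample: int | None = None,
    seed: int = 0,
) -> CorrelationReport:
    """Correlate every pair of sample profiles over their shared drugs.

    For samples j and k only the drugs observed in both are used; profile
    means are taken over those shared drugs. Pairs with fewer than
    ``min_shared`` shared drugs, or with a zero-variance profile over them,
    are reported undefined (with a reason) and excluded from summaries.
    ``subsample`` caps the number of pairs (without replacement, seeded) for
    very large screens.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    samples = matrix.sample_ids
    values = matrix.values.to_numpy()
    observed = np.isfinite(values)

    pair_list = list(itertools.combinations(range(len(samples)), 2))
    if subsample is not None and subsample < len(pair_list):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pair_list), size=subsample, replace=False)
        pair_list = [pair_list[i] for i in sorted(idx)]

    rows = []
    for j, k in pair_list:
        shared = observed[j] & observed[k]
        n_shared = int(shared.sum())
        row = {
            "sample_j": samples[j],
            "sample_k": samples[k],
            "n_shared": n_shared,
            "pearson": np.nan,
            "spearman": np.nan,
            "reason": "",
        }
        if n_shared < min_shared:
            row["reason"] = f"only {n_shared} shared drugs (< {min_shared})"
        else:
            a, b = values[j, shared], values[k, shared]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                row["reason"] = "zero variance over shared drugs"
            else:
                row["pearson"] = float(stats.pearsonr(a, b).statistic)
                row["spearman"] = float(stats.spearmanr(a, b).statistic)
        rows.append(row)
    pairs = pd.DataFrame(
        rows, columns=["sample_j", "sample_k", "n_shared", "pearson", "spearman", "reason"]
    )
    return CorrelationReport(
        pairs, method=method, measure_name=matrix.measure.name, min_shared=min_shared
    )


def stratify_correlations(
    report: CorrelationReport,
    annotation: SubtypeAnnotation,
    by: str = "within_vs_between",
) -> dict:
    """Split pair correlations by sample subtype.

    ``by="within_vs_between"`` groups pairs into same-subtype and
    different-subtype; ``by="subtype_pair"`` gives the full subtype-pair
    grid. Pairs with an unannotated sample are ignored.
    """
    if by not in ("within_vs_between", "subtype_pair"):
        raise ValueError("by must be 'within_vs_between' or 'subtype_pair'")
    labels = annotation.sample_subtype.dropna()
    if labels.empty:
        raise ValueError("annotation contains no sample subtypes")
    pairs = report.pairs
    annotated = pairs["sample_j"].isin(labels.index) & pairs["sample_k"].isin(labels.index)
    pairs = pairs[annotated]
    lab_j = pairs["sample_j"].map(labels)
    lab_k = pairs["sample_k"].map(labels)
    if labels.nunique() < 2:
        warnings.warn("all samples share one subtype; within-subtype summary only", stacklevel=2)

    col = report.method
    out: dict = {}
    if by == "within_vs_between":
        within = pairs[lab_j.eq(lab_k)]
        between = pairs[~lab_j.eq(lab_k)]
        out["within"] = _summary(within[col])
        out["between"] = _summary(between[col])
    else:
        key = [tuple(sorted(t)) for t in zip(lab_j, lab_k)]
        for name, grp in pairs.groupby(pd.Series(key, index=pairs.index)):
            out[name] = _summary(grp[col])
    report.strata[by] = out
    return out


def pathway_restricted_correlation(
    matrix: ResponseMatrix,
    annotation: SubtypeAnnotation,
    pathway,
    method: str = "pearson",
    min_shared: int = MIN_SHARED,
) -> CorrelationReport:
    """The same pairwise computation restricted to one drug pathway."""
    drugs = [d for d in annotation.drugs_in_pathway(pathway) if d in set(matrix.drug_ids)]
    report = pairwise_profile_correlation(
        matrix.restrict_drugs(drugs), method=method, min_shared=min_shared
    )
    report.measure_name = f"{matrix.measure.name}|{pathway}"
    return report
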
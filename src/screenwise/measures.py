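"""Per-drug z-scoring of response matrices and expression harmonization.

The per-drug z-score ``Z[i, j] = (x[i, j] - mean_i) / sd_i`` standardizes
each drug's responses across all samples it was tested on. It removes the
drug's intrinsic potency/toxicity from the measure, turning absolute
response into *relative* sensitivity of a sample compared with the average
sample — the transformation this package exists to study.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ResponseMatrix, validate_expression

__all__ = ["zscore_by_drug", "harmonize_expression", "validate_external_zscores"]

#: drugs observed fewer times than this are dropped before z-scoring —
#: a standard deviation over fewer points is meaningless
MIN_OBS = 3


def zscore_by_drug(matrix: ResponseMatrix, min_obs: int = MIN_OBS, ddof: int = 0) -> ResponseMatrix:
    """Z-score each drug column across the samples it was tested on.

    Uses the population standard deviation (``ddof=0``) by default, i.e. the
    full set of screened samples is the reference population. Drugs with
    fewer than ``min_obs`` observed values or zero variance are dropped with
    a warning naming them — never silently zeroed. The missing mask is
    preserved.
    """
    values = matrix.values
    counts = values.notna().sum(axis=0)
    sds = values.std(axis=0, ddof=ddof)

    too_few = list(counts.index[counts < min_obs])
    constant = [d for d in counts.index[(counts >= min_obs)] if sds[d] == 0]
    if too_few:
        warnings.warn(
            f"dropping {len(too_few)} drug(s) with fewer than {min_obs} observations: {too_few}",
            stacklevel=2,
        )
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant drug column(s): {constant}", stacklevel=2
        )
    keep = [d for d in values.columns if d not in set(too_few) | set(constant)]
    kept = values[keep]
    z = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=ddof)
    return ResponseMatrix(z, matrix.measure.zscored())


def _zscore_genes(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    sd = expr.std(axis=0, ddof=ddof)
    zero = list(sd.index[sd == 0])
    if zero:
        warnings.warn(f"dropping {len(zero)} zero-variance gene(s): {zero[:10]}", stacklevel=3)
        expr = expr.drop(columns=zero)
        sd = sd.drop(zero)
    return (expr - expr.mean(axis=0)) / sd


def harmonize_expression(
    train_expr: pd.DataFrame, test_expr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Make two expression datasets comparable (double z-score).

    Restricts both to the shared genes, z-scores each dataset separately per
    gene, concatenates, then z-scores the merged matrix per gene once more.
    Returns the merged matrix and a per-row provenance label
    (``"train"``/``"test"``).
    """
    train_expr = validate_expression(train_expr)
    test_expr = validate_expression(test_expr)
    shared = [g for g in train_expr.columns if g in set(test_expr.columns)]
    if not shared:
        raise ValueError("no shared genes between the two expression datasets")
    overlap = set(train_expr.index) & set(test_expr.index)
    if overlap:
        raise ValueError(f"sample ids appear in both datasets: {sorted(overlap)[:5]}")
    z_train = _zscore_genes(train_expr[shared])
    z_test = _zscore_genes(test_expr[shared])
    shared = [g for g in z_train.columns if g in set(z_test.columns)]
    merged = pd.concat([z_train[shared], z_test[shared]], axis=0)
    merged = _zscore_genes(merged)
    origin = pd.Series(
        ["train"] * len(train_expr) + ["test"] * len(test_expr),
        index=list(train_expr.index) + list(test_expr.index),
        name="origin",
    )
    return merged, origin.loc[merged.index]


def validate_external_zscores(
    matrix: ResponseMatrix, external: pd.DataFrame, rtol: float = 1e-6
) -> bool:
    """Check that externally provided z-scores match recomputation.

    Recomputes per-drug z-scores across all samples and compares with the
    ``external`` frame on the shared cells at relative tolerance ``rtol``.
    """
    recomputed = zscore_by_drug(matrix).values
    shared_drugs = [d for d in recomputed.columns if d in set(external.columns)]
    shared_samples = [s for s in recomputed.index if s in set(external.index)]
    if not shared_drugs or not shared_samples:
        raise ValueError("external z-scores share no cells with the matrix")
    a = recomputed.loc[shared_samples, shared_drugs].to_numpy()
    b = external.loc[shared_samples, shared_drugs].to_numpy(dtype=float)
    both = np.isfinite(a) & np.isfinite(b)
    return bool(np.allclose(a[both], b[both], rtol=rtol, atol=1e-12))
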
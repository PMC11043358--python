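"""Loader shims for public pharmacogenomic portal exports.

Thin converters from the column layouts of the public downloads (GDSC
fitted-dose-response CSV, DepMap/CCLE expression CSV, CTRP v2 AUC tables,
organoid-library AUC sheets exported to CSV) into the package's containers.
They only reshape columns — no network access, no unit conversion beyond
what is noted — and are provided for users with local copies of the public
files; the shipped tests exercise the synthetic pipeline instead.
"""
from __future__ import annotations

import pandas as pd

from .containers import AUC as AUC_TAG
from .containers import LN_IC50, ResponseMatrix, validate_expression

__all__ = [
    "response_from_gdsc",
    "response_from_ctrp",
    "response_from_long_table",
    "expression_from_depmap",
]


def response_from_long_table(
    frame: pd.DataFrame, sample_col: str, drug_col: str, value_col: str, measure
) -> ResponseMatrix:
    """Pivot any long (sample, drug, value) table into a ResponseMatrix."""
    dup = frame.duplicated([sample_col, drug_col])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (sample, drug) rows; aggregate before loading"
        )
    wide = frame.pivot(index=sample_col, columns=drug_col, values=value_col)
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    return ResponseMatrix(wide.sort_index(axis=0).sort_index(axis=1), measure)


def response_from_gdsc(path) -> ResponseMatrix:
    """GDSC fitted dose-response export (``LN_IC50`` per cell line x drug)."""
    frame = pd.read_csv(path)
    cols = {c.upper(): c for c in frame.columns}
    needed = ["CELL_LINE_NAME", "DRUG_NAME", "LN_IC50"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"not a GDSC fitted-dose-response export; missing {missing}")
    sub = frame[[cols[c] for c in needed]].dropna()
    # replicate screenings of the same drug on the same line are averaged
    sub = sub.groupby([cols["CELL_LINE_NAME"], cols["DRUG_NAME"]], as_index=False).mean()
    return response_from_long_table(sub, cols["CELL_LINE_NAME"], cols["DRUG_NAME"],
                                    cols["LN_IC50"], LN_IC50)


def response_from_ctrp(path) -> ResponseMatrix:
    """CTRP v2 per-experiment AUC table (``area_under_curve`` column)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    needed = ["ccl_name", "cpd_name", "area_under_curve"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"not a CTRP AUC table; missing {missing}")
    sub = frame[needed].dropna().groupby(["ccl_name", "cpd_name"], as_index=False).mean()
    return response_from_long_table(sub, "ccl_name", "cpd_name", "area_under_curve", AUC_TAG)


def expression_from_depmap(path) -> pd.DataFrame:
    """DepMap/CCLE expression matrix CSV (cell lines as rows, genes as columns).

    Gene headers like ``TP53 (7157)`` are trimmed to the symbol.
    """
    frame = pd.read_csv(path, index_col=0)
    frame.columns = [str(c).split(" (")[0] for c in frame.columns]
    frame = frame.loc[:, ~frame.columns.duplicated()]
    return validate_expression(frame)
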
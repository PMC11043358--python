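"""In-memory containers shared across the package.

A screen is held as three aligned tables: a samples x drugs
:class:`ResponseMatrix` of one drug-response measure (with explicit
missingness), a samples x genes expression ``DataFrame``, and a
:class:`DrugFeatureSet` of binary fingerprints. Sample subtypes and drug
target-pathways live in a :class:`SubtypeAnnotation`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeasureTag",
    "LN_IC50",
    "AUC",
    "AUC_NORM",
    "DRS",
    "ResponseMatrix",
    "DrugFeatureSet",
    "SubtypeAnnotation",
    "validate_expression",
]


@dataclass(frozen=True)
class MeasureTag:
    """Names a drug-response measure and its ranking direction.

    For every shipped measure (ln-IC50, AUC, normalized AUC, drug relevance
    score, and their per-drug z-scores) a *lower* value means the sample is
    *more* sensitive to the drug.
    """

    name: str
    lower_is_more_sensitive: bool = True

    def zscored(self) -> "MeasureTag":
        """Tag for the per-drug z-score of this measure (same direction)."""
        return MeasureTag(f"ZSCORE({self.name})", self.lower_is_more_sensitive)

    @property
    def is_zscore(self) -> bool:
        return self.name.startswith("ZSCORE(")


LN_IC50 = MeasureTag("LN_IC50")
AUC = MeasureTag("AUC")
AUC_NORM = MeasureTag("AUC_NORM")
DRS = MeasureTag("DRS")


def _check_unique(ids, kind: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {kind} ids: {dups}")


class ResponseMatrix:
    """Samples x drugs matrix of one response measure with a missing mask.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with drug ids as columns. ``NaN``
        marks a (sample, drug) pair that was not screened.
    measure
        The :class:`MeasureTag` describing what the values are.
    """

    def __init__(self, values: pd.DataFrame, measure: MeasureTag):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        _check_unique(values.index, "sample")
        _check_unique(values.columns, "drug")
        self.values = values.astype(float)
        self.values.index.name = "sample_id"
        self.measure = measure

    # -- basic geometry -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def drug_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is missing."""
        return self.values.isna()

    def observed_per_drug(self) -> pd.Series:
        return self.values.notna().sum(axis=0)

    # -- views ----------------------------------------------------------
    def restrict_samples(self, sample_ids) -> "ResponseMatrix":
        return ResponseMatrix(self.values.loc[list(sample_ids)].copy(), self.measure)

    def restrict_drugs(self, drug_ids) -> "ResponseMatrix":
        return ResponseMatrix(self.values[list(drug_ids)].copy(), self.measure)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.values.copy(), self.measure)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ResponseMatrix({self.n_samples} samples x {self.n_drugs} drugs, "
            f"measure={self.measure.name})"
        )


class DrugFeatureSet:
    """Per-drug binary fingerprints, optionally with SMILES strings."""

    def __init__(self, fingerprints: pd.DataFrame, smiles: dict[str, str] | None = None):
        _check_unique(fingerprints.index, "drug")
        arr = fingerprints.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprints must be binary (0/1)")
        self.fingerprints = fingerprints.astype(np.int8)
        self.fingerprints.index.name = "drug_id"
        self.smiles = dict(smiles) if smiles else {}

    @property
    def drug_ids(self) -> list:
        return list(self.fingerprints.index)

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    def matrix(self, drug_ids=None) -> np.ndarray:
        if drug_ids is None:
            return self.fingerprints.to_numpy()
        missing = [d for d in drug_ids if d not in self.fingerprints.index]
        if missing:
            raise KeyError(f"no fingerprint for drugs: {missing}")
        return self.fingerprints.loc[list(drug_ids)].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DrugFeatureSet({len(self.drug_ids)} drugs x {self.n_bits} bits)"


@dataclass
class SubtypeAnnotation:
    """Sample -> subtype and drug -> target-pathway labels (partial allowed)."""

    sample_subtype: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    drug_pathway: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        self.sample_subtype = pd.Series(self.sample_subtype, dtype=object)
        self.drug_pathway = pd.Series(self.drug_pathway, dtype=object)
        _check_unique(self.sample_subtype.index, "annotated sample")
        _check_unique(self.drug_pathway.index, "annotated drug")

    def subtypes(self) -> list:
        return sorted(self.sample_subtype.dropna().unique())

    def pathways(self) -> list:
        return sorted(self.drug_pathway.dropna().unique())

    def drugs_in_pathway(self, pathway) -> list:
        if pathway not in set(self.drug_pathway.values):
            raise KeyError(f"unknown pathway: {pathway!r}")
        return list(self.drug_pathway.index[self.drug_pathway == pathway])


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x genes expression frame and coerce to float."""
    _check_unique(expr.index, "sample")
    _check_unique(expr.columns, "gene")
    out = expr.astype(float)
    out.index.name = "sample_id"
    return out
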
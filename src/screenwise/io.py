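"""Readers and writers for the on-disk formats.

Matrices are wide CSV (first column ``sample_id``, drug or gene ids as
header, empty cell = missing); long-format tables and annotations are TSV;
ground truth and reports are JSON. Floats are written with Python's
shortest-repr formatting, so write(read(x)) is byte-identical for files in
canonical form. The column layouts match the public GDSC/DepMap export
dialects, so real screen exports load through the same readers.
"""
from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DrugFeatureSet,
    LN_IC50,
    MeasureTag,
    ResponseMatrix,
    SubtypeAnnotation,
    validate_expression,
)
from .dose_response import DoseResponseCurve

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_expression",
    "write_expression",
    "read_fingerprints",
    "write_fingerprints",
    "read_smiles",
    "read_annotations",
    "read_dose_response",
    "curves_from_frame",
    "write_dose_response",
    "write_truth",
    "fingerprints_from_smiles",
]

logger = logging.getLogger(__name__)


def _fmt(value: float) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return repr(float(value))


def _read_table(path, delimiter: str) -> list[list[str]]:
    with open(path, newline="") as fh:
        return list(csv.reader(fh, delimiter=delimiter))


def _parse_matrix(path, delimiter: str) -> pd.DataFrame:
    rows = _read_table(path, delimiter)
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dup = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise ValueError(f"{path}: duplicate column ids {dup}")
    data, index = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}: line {r} has {len(row)} fields, expected {len(header)}")
        index.append(row[0])
        parsed = []
        for c, cell in enumerate(row[1:], start=2):
            if cell == "":
                parsed.append(np.nan)
            else:
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {r}, column {header[c - 1]!r}"
                    ) from None
        data.append(parsed)
    if len(set(index)) != len(index):
        dup = sorted({s for s in index if index.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    return pd.DataFrame(data, index=index, columns=col_ids)


def _write_matrix(frame: pd.DataFrame, path, delimiter: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sample_id"] + list(frame.columns))
        for sid, row in frame.iterrows():
            writer.writerow([sid] + [_fmt(v) for v in row])


def read_response_matrix(path, measure: MeasureTag = LN_IC50) -> ResponseMatrix:
    """Read a wide CSV response matrix (empty cell = missing)."""
    return ResponseMatrix(_parse_matrix(path, ","), measure)


def write_response_matrix(matrix: ResponseMatrix, path) -> None:
    _write_matrix(matrix.values, path, ",")


def read_expression(path) -> pd.DataFrame:
    """Read a samples x genes expression TSV (genes as columns)."""
    return validate_expression(_parse_matrix(path, "\t"))


def write_expression(expr: pd.DataFrame, path) -> None:
    _write_matrix(expr, path, "\t")


def read_fingerprints(path) -> DrugFeatureSet:
    """Read a drug_id<TAB>bitstring table of binary fingerprints."""
    rows = _read_table(path, "\t")
    ids, bits = [], []
    start = 1 if rows and rows[0][:1] == ["drug_id"] else 0
    for r, row in enumerate(rows[start:], start=start + 1):
        if len(row) != 2:
            raise ValueError(f"{path}: line {r} must be drug_id<TAB>bitstring")
        drug, bitstring = row
        bad = set(bitstring) - {"0", "1"}
        if bad:
            raise ValueError(f"{path}: line {r} has non-binary characters {sorted(bad)}")
        if bits and len(bitstring) != len(bits[0]):
            raise ValueError(
                f"{path}: line {r}: fingerprint length {len(bitstring)} != {len(bits[0])}"
            )
        ids.append(drug)
        bits.append([int(ch) for ch in bitstring])
    return DrugFeatureSet(pd.DataFrame(bits, index=ids, dtype=np.int8))


def write_fingerprints(drugs: DrugFeatureSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_id", "fingerprint"])
        for drug in drugs.drug_ids:
            bits = "".join(map(str, drugs.fingerprints.loc[drug]))
            writer.writerow([drug, bits])


def read_smiles(path) -> dict[str, str]:
    """Read a drug_id<TAB>smiles table."""
    rows = _read_table(path, "\t")
    start = 1 if rows and rows[0][:1] == ["drug_id"] else 0
    out = {}
    for r, row in enumerate(rows[start:], start=start + 1):
        if len(row) != 2:
            raise ValueError(f"{path}: line {r} must be drug_id<TAB>smiles")
        if row[0] in out:
            raise ValueError(f"{path}: duplicate drug id {row[0]!r}")
        out[row[0]] = row[1]
    return out


def read_annotations(
    sample_path=None, drug_path=None, known_samples=None, known_drugs=None
) -> SubtypeAnnotation:
    """Read sample-subtype and drug-pathway TSVs (id<TAB>label).

    Rows referencing unknown ids (when a known-id list is given) are skipped
    with a warning.
    """

    def load(path, known, kind):
        if path is None:
            return pd.Series(dtype=object)
        rows = _read_table(path, "\t")
        start = 1 if rows and rows[0] and rows[0][1:2] == ["label"] else 0
        ids, labels = [], []
        for r, row in enumerate(rows[start:], start=start + 1):
            if len(row) != 2:
                raise ValueError(f"{path}: line {r} must be id<TAB>label")
            if known is not None and row[0] not in known:
                warnings.warn(f"{path}: line {r} references unknown {kind} {row[0]!r}; skipped")
                continue
            ids.append(row[0])
            labels.append(row[1])
        return pd.Series(labels, index=ids, dtype=object)

    return SubtypeAnnotation(
        sample_subtype=load(sample_path, known_samples, "sample"),
        drug_pathway=load(drug_path, known_drugs, "drug"),
    )


def read_dose_response(path) -> list[DoseResponseCurve]:
    """Read the long-format dose-response TSV into per-pair curves."""
    table = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "drug_id", "concentration_uM", "viability"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return curves_from_frame(table)


def curves_from_frame(table: pd.DataFrame) -> list[DoseResponseCurve]:
    """Group a long-format dose-response frame into per-pair curves."""
    curves = []
    for (sid, did), grp in table.groupby(["sample_id", "drug_id"], sort=True):
        grp = grp.sort_values("concentration_uM")
        curves.append(
            DoseResponseCurve(
                sample_id=sid,
                drug_id=did,
                concentrations=grp["concentration_uM"].to_numpy(),
                viability=grp["viability"].to_numpy(),
            )
        )
    return curves


def write_dose_response(table: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "drug_id", "concentration_uM", "viability"])
        for row in table.itertuples(index=False):
            writer.writerow(
                [row.sample_id, row.drug_id, _fmt(row.concentration_uM), _fmt(row.viability)]
            )


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1, sort_keys=True) + "\n")


def fingerprints_from_smiles(
    smiles: dict[str, str], radius: int = 2, n_bits: int = 2048
) -> DrugFeatureSet:
    """Morgan fingerprints from SMILES via RDKit (radius 2, 2048 bits)."""
    from rdkit import Chem  # optional dependency, imported lazily
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, ids = [], []
    for drug, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {drug!r}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0"))
        ids.append(drug)
    frame = pd.DataFrame(np.vstack(rows).astype(np.int8), index=ids)
    return DrugFeatureSet(frame, smiles=smiles)
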
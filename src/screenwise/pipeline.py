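"""Pipeline orchestrator: simulate -> derive measures -> correlate ->
select genes -> fit/evaluate models, any subset selectable, with provenance.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import AUC_NORM, LN_IC50
from .correlation import pairwise_profile_correlation, stratify_correlations
from .dose_response import curves_to_matrix
from .evaluation import run_setting_matrix
from .gene_selection import threshold_sweep
from .io import (
    read_dose_response,
    write_dose_response,
    write_expression,
    write_fingerprints,
    write_response_matrix,
    write_truth,
)
from .measures import zscore_by_drug
from .simulate import SyntheticScreenConfig, generate_screen

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "curves", "zscore", "correlate", "select_genes", "evaluate")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    screen: dict = field(default_factory=dict)  # SyntheticScreenConfig overrides
    measure: str = "LN_IC50"  # LN_IC50 or AUC_NORM
    models: tuple = ("mean", "knn")
    n_folds: int = 5
    k: int = 5
    min_shared: int = 10
    sweep_drug: str | None = None  # drug id for the gene-selection stage
    dose_response_path: str | None = None  # input when 'simulate' is skipped

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.measure not in ("LN_IC50", "AUC_NORM"):
            raise ValueError("measure must be LN_IC50 or AUC_NORM")
        if "simulate" not in self.stages:
            if not self.dose_response_path:
                raise ValueError("dose_response_path required when 'simulate' is skipped")
            if not Path(self.dose_response_path).exists():
                raise FileNotFoundError(self.dose_response_path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        raw["models"] = tuple(raw.get("models", ("mean", "knn")))
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; all outputs under ``config.out_dir``.

    Writes a provenance file (config hash, seeds, package version) and logs
    every dropped drug or sample. A stage failure aborts with the stage name
    while keeping the outputs of completed stages on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("screenwise")
    root.addHandler(handler)
    stage = None
    try:
        bundle = None
        matrix = None
        if "simulate" in config.stages:
            stage = "simulate"
            screen_cfg = SyntheticScreenConfig(**{"seed": config.seed, **config.screen})
            bundle = generate_screen(screen_cfg)
            write_expression(bundle.expression, out / "expression.tsv")
            write_dose_response(bundle.dose_response, out / "dose_response.tsv")
            write_fingerprints(bundle.drug_features, out / "fingerprints.tsv")
            write_truth(bundle.truth, out / "truth.json")
            _write_annotation(bundle.annotation, out)

        if "curves" in config.stages:
            stage = "curves"
            if bundle is not None:
                curves = read_dose_response(out / "dose_response.tsv")
            else:
                curves = read_dose_response(config.dose_response_path)
            measure = LN_IC50 if config.measure == "LN_IC50" else AUC_NORM
            matrix = curves_to_matrix(curves, measure)
            write_response_matrix(matrix, out / f"response_{measure.name.lower()}.csv")

        if "zscore" in config.stages:
            stage = "zscore"
            if matrix is None:
                raise RuntimeError("zscore stage needs the curves stage")
            zmatrix = zscore_by_drug(matrix)
            write_response_matrix(zmatrix, out / "response_zscored.csv")

        if "correlate" in config.stages:
            stage = "correlate"
            if matrix is None:
                raise RuntimeError("correlate stage needs the curves stage")
            summaries = {}
            for label, mat in (("raw", matrix), ("zscored", zscore_by_drug(matrix))):
                report = pairwise_profile_correlation(mat, min_shared=config.min_shared)
                report.to_tsv(out / f"correlations_{label}.tsv")
                summaries[label] = report.summary()
                if bundle is not None:
                    summaries[f"{label}_by_subtype"] = stratify_correlations(
                        report, bundle.annotation
                    )
            (out / "correlation_summary.json").write_text(
                json.dumps(summaries, indent=1, sort_keys=True) + "\n"
            )

        if "select_genes" in config.stages:
            stage = "select_genes"
            if bundle is None or matrix is None:
                raise RuntimeError("select_genes stage needs simulate and curves stages")
            drug = config.sweep_drug or matrix.drug_ids[0]
            zmatrix = zscore_by_drug(matrix)
            result = threshold_sweep(
                bundle.expression, zmatrix.values[drug], seed=config.seed, drug_id=drug
            )
            (out / f"gene_selection_{drug}.json").write_text(
                json.dumps(result.to_jsonable(), indent=1, sort_keys=True) + "\n"
            )

        if "evaluate" in config.stages:
            stage = "evaluate"
            if bundle is None or matrix is None:
                raise RuntimeError("evaluate stage needs simulate and curves stages")
            report = run_setting_matrix(
                matrix,
                bundle.expression,
                bundle.drug_features,
                models=config.models,
                n_folds=config.n_folds,
                k=config.k,
                seed=config.seed,
            )
            report.to_tsv(out / "evaluation.tsv")
            agg = report.aggregate()
            agg.to_csv(out / "evaluation_aggregate.tsv", sep="\t", index=False)

        provenance = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "stages_completed": list(config.stages),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True, default=str) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _write_annotation(annotation, out: Path) -> None:
    for name, series in (
        ("sample_subtypes", annotation.sample_subtype),
        ("drug_pathways", annotation.drug_pathway),
    ):
        frame = pd.DataFrame({"id": series.index, "label": series.values})
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False, header=["id", "label"])
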
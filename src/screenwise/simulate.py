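"""Synthetic pharmacogenomic screen generator.

Emulates the statistical structure of large viability screens such as GDSC:
a wide spread of per-drug mean potencies, a per-sample general-sensitivity
factor (multi-drug resistance), a small gene-driven per-(sample, drug)
signal, per-(subtype, drug) effects, assay noise, and partial drug coverage
per sample. Viability follows a two-parameter log-logistic (Hill) curve with
asymptotes 1 and 0, so the true ln-IC50 is analytically recoverable, which
makes every downstream stage testable without external data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DrugFeatureSet, SubtypeAnnotation, validate_expression

__all__ = [
    "SyntheticScreenConfig",
    "SyntheticTruth",
    "ScreenBundle",
    "generate_screen",
    "generate_transfer_pair",
    "hill_viability",
]

_DEFAULT_DOSE_GRID = tuple(np.logspace(-3.0, 3.0, 9))

#: small built-in molecule list for optional SMILES emission: common
#: anti-cancer and reference compounds, cycled over the drug panel
BUILTIN_SMILES = (
    "CC(=O)Oc1ccccc1C(=O)O",                     # aspirin
    "CN1CCC[C@H]1c1cccnc1",                      # nicotine
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                # ibuprofen
    "Clc1ccccc1C2=NCC(=O)Nc3ccc(cc23)[N+](=O)[O-]",  # clonazepam-like core
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                # procainamide
    "NC(=O)c1ccc[nH]1",                          # pyrrole carboxamide
    "OC(=O)c1ccccc1O",                           # salicylic acid
    "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1",            # cytidine analog
    "CC(=O)Nc1ccc(O)cc1",                        # paracetamol
    "OCC1OC(O)C(O)C(O)C1O",                      # glucose
    "Nc1ncnc2[nH]cnc12",                         # adenine
)


def builtin_smiles_for(drug_ids) -> dict[str, str]:
    """Assign molecules from the built-in list to drug ids, cycling."""
    return {d: BUILTIN_SMILES[i % len(BUILTIN_SMILES)] for i, d in enumerate(drug_ids)}


def hill_viability(conc: np.ndarray, ln_ic50, hill_slope) -> np.ndarray:
    """Fraction of surviving cells at concentration ``conc`` (uM).

    Two-parameter log-logistic curve with upper asymptote 1 and lower
    asymptote 0: ``v(c) = 1 / (1 + (c / IC50)^h)``.
    """
    lnc = np.log(np.asarray(conc, dtype=float))
    return 1.0 / (1.0 + np.exp(np.multiply(hill_slope, lnc - ln_ic50)))


@dataclass
class SyntheticScreenConfig:
    """Parameters of one synthetic screen.

    Standard deviations are on the natural-log IC50 scale (log-concentration
    units). Defaults reproduce a drug-dominated screen: the between-drug
    potency spread (``drug_potency_sd = 2.0``) is large against the
    per-sample factor (0.5), the gene-driven signal (0.2) and the assay
    noise (0.05).
    """

    n_samples: int = 50
    n_drugs: int = 30
    n_genes: int = 200
    causal_genes_per_drug: int = 10
    drug_potency_sd: float = 2.0
    sample_factor_sd: float = 0.5
    genetic_effect_sd: float = 0.2
    noise_sd: float = 0.05
    hill_slope: float = 1.0
    dose_grid: tuple = _DEFAULT_DOSE_GRID
    coverage_fraction: float = 0.9
    coverage_sd: float = 0.05
    n_subtypes: int = 4
    subtype_effect_sd: float = 0.3
    n_pathways: int = 5
    fingerprint_bits: int = 256
    emit_smiles: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_drugs", "n_genes", "causal_genes_per_drug"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "drug_potency_sd",
            "sample_factor_sd",
            "genetic_effect_sd",
            "noise_sd",
            "coverage_sd",
            "subtype_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")
        grid = np.asarray(self.dose_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2:
            raise ValueError("dose_grid needs >= 2 concentrations")
        if (grid <= 0).any() or (np.diff(grid) <= 0).any():
            raise ValueError("dose_grid must be strictly increasing and positive")
        if self.causal_genes_per_drug > self.n_genes:
            raise ValueError("causal_genes_per_drug exceeds n_genes")
        self.dose_grid = tuple(grid)


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_screen`.

    ``true_log_ic50[j, i] = mu_drug[i] + sample_factor[j]
    + subtype_effect[subtype(j), i] + sum_g causal_weights[i][g] * expr[j, g]``
    exactly, before assay noise.
    """

    mu_drug: pd.Series
    sample_factor: pd.Series
    causal_gene_ids: dict[str, list]
    causal_weights: dict[str, np.ndarray]
    true_log_ic50: pd.DataFrame
    subtype_effect: pd.DataFrame = None
    hill_slope: float = 1.0

    def to_jsonable(self) -> dict:
        return {
            "mu_drug": self.mu_drug.to_dict(),
            "sample_factor": self.sample_factor.to_dict(),
            "causal_gene_ids": {d: list(g) for d, g in self.causal_gene_ids.items()},
            "causal_weights": {d: list(map(float, w)) for d, w in self.causal_weights.items()},
            "true_log_ic50": self.true_log_ic50.to_dict(),
            "subtype_effect": self.subtype_effect.to_dict() if self.subtype_effect is not None else None,
            "hill_slope": float(self.hill_slope),
        }


@dataclass
class ScreenBundle:
    """One generated screen: everything downstream stages consume."""

    expression: pd.DataFrame
    dose_response: pd.DataFrame  # long: sample_id, drug_id, concentration_uM, viability
    drug_features: DrugFeatureSet
    annotation: SubtypeAnnotation
    truth: SyntheticTruth
    config: SyntheticScreenConfig = field(repr=False, default=None)

    def __iter__(self):  # allows tuple-unpacking the five public artifacts
        return iter(
            (self.expression, self.dose_response, self.drug_features, self.annotation, self.truth)
        )


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) matched to (mean, sd); sd is shrunk if infeasible."""
    max_var = mean * (1 - mean)
    var = min(sd**2, 0.9 * max_var) if max_var > 0 else 0.0
    if var <= 0:
        return np.inf, np.inf  # sentinel: degenerate at the mean
    nu = max_var / var - 1.0
    return mean * nu, (1 - mean) * nu


def _make_fingerprints(rng, drug_ids, pathway_of, n_pathways, n_bits) -> pd.DataFrame:
    """Binary fingerprints where drugs of one pathway share a bit-block."""
    block = max(4, n_bits // (4 * max(n_pathways, 1)))
    if block * n_pathways > n_bits:
        raise ValueError("fingerprint_bits too small for the pathway blocks")
    fp = (rng.random((len(drug_ids), n_bits)) < 0.15).astype(np.int8)
    pathway_patterns = (rng.random((n_pathways, block)) < 0.7).astype(np.int8)
    for row, drug in enumerate(drug_ids):
        p = pathway_of[drug]
        fp[row, p * block : (p + 1) * block] = pathway_patterns[p]
    return pd.DataFrame(fp, index=drug_ids)


def generate_screen(
    config: SyntheticScreenConfig,
    *,
    drug_truth: SyntheticTruth | None = None,
    drug_features: DrugFeatureSet | None = None,
) -> ScreenBundle:
    """Generate one synthetic screen, fully reproducible from ``config.seed``.

    Pass ``drug_truth``/``drug_features`` from a previous screen to reuse its
    drug-level structure (mean potencies, causal genes and weights,
    fingerprints) with fresh samples — the setting of a zero-shot transfer
    experiment between two datasets screening the same drug panel.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m, n, g = cfg.n_samples, cfg.n_drugs, cfg.n_genes

    sample_ids = [f"S{j:04d}" for j in range(m)]
    drug_ids = [f"D{i:03d}" for i in range(n)]
    gene_ids = [f"G{k:05d}" for k in range(g)]

    expr = pd.DataFrame(rng.standard_normal((m, g)), index=sample_ids, columns=gene_ids)
    expr = validate_expression(expr)

    subtype_labels = [f"subtype{j % cfg.n_subtypes}" for j in range(m)]
    pathway_of = {d: i % cfg.n_pathways for i, d in enumerate(drug_ids)}

    if drug_truth is None:
        mu = rng.normal(0.0, cfg.drug_potency_sd, n)
        causal_ids: dict[str, list] = {}
        causal_w: dict[str, np.ndarray] = {}
        for d in drug_ids:
            idx = np.sort(rng.choice(g, size=cfg.causal_genes_per_drug, replace=False))
            # bounded-away-from-zero magnitudes: every planted gene carries
            # signal of comparable scale (mean |w| = genetic_effect_sd)
            w = (
                cfg.genetic_effect_sd
                * rng.uniform(0.5, 1.5, len(idx))
                * rng.choice([-1.0, 1.0], len(idx))
            )
            causal_ids[d] = [gene_ids[k] for k in idx]
            causal_w[d] = w
        subtype_eff = pd.DataFrame(
            rng.normal(0.0, cfg.subtype_effect_sd, (cfg.n_subtypes, n)),
            index=[f"subtype{t}" for t in range(cfg.n_subtypes)],
            columns=drug_ids,
        )
    else:
        if list(drug_truth.mu_drug.index) != drug_ids:
            raise ValueError("drug_truth panel does not match config.n_drugs")
        mu = drug_truth.mu_drug.to_numpy()
        causal_ids = drug_truth.causal_gene_ids
        causal_w = drug_truth.causal_weights
        for d in drug_ids:
            if any(gid not in set(gene_ids) for gid in causal_ids[d]):
                raise ValueError("drug_truth causal genes absent from this gene panel")
        subtype_eff = drug_truth.subtype_effect
        if subtype_eff is None or subtype_eff.shape[0] != cfg.n_subtypes:
            subtype_eff = pd.DataFrame(
                rng.normal(0.0, cfg.subtype_effect_sd, (cfg.n_subtypes, n)),
                index=[f"subtype{t}" for t in range(cfg.n_subtypes)],
                columns=drug_ids,
            )

    sample_factor = rng.normal(0.0, cfg.sample_factor_sd, m)

    gene_pos = {gid: k for k, gid in enumerate(gene_ids)}
    genetic = np.zeros((m, n))
    for i, d in enumerate(drug_ids):
        cols = [gene_pos[gid] for gid in causal_ids[d]]
        genetic[:, i] = expr.to_numpy()[:, cols] @ causal_w[d]

    subtype_term = subtype_eff.loc[subtype_labels].to_numpy()
    true_ln_ic50 = mu[None, :] + sample_factor[:, None] + subtype_term + genetic

    grid = np.asarray(cfg.dose_grid)
    if (np.exp(true_ln_ic50) < grid[0]).all() or (np.exp(true_ln_ic50) > grid[-1]).all():
        warnings.warn(
            "dose grid does not cover any planted IC50; all curves will be extrapolated",
            stacklevel=2,
        )

    # partial drug coverage: per-sample Bernoulli drop with Beta-drawn rate
    if cfg.coverage_fraction >= 1.0:
        observed = np.ones((m, n), dtype=bool)
    else:
        a, b = _beta_params(cfg.coverage_fraction, cfg.coverage_sd)
        p_sample = (
            np.full(m, cfg.coverage_fraction) if not np.isfinite(a) else rng.beta(a, b, m)
        )
        observed = rng.random((m, n)) < p_sample[:, None]
        for j in range(m):  # every sample keeps at least one drug
            if not observed[j].any():
                observed[j, int(rng.integers(n))] = True

    # long-format dose-response table over observed (sample, drug) pairs
    rows_j, cols_i = np.nonzero(observed)
    n_pairs = len(rows_j)
    lnc = np.log(grid)
    viab = 1.0 / (
        1.0 + np.exp(cfg.hill_slope * (lnc[None, :] - true_ln_ic50[rows_j, cols_i][:, None]))
    )
    if cfg.noise_sd > 0:
        viab = viab + rng.normal(0.0, cfg.noise_sd, viab.shape)
    viab = np.clip(viab, 0.0, 1.2)
    dose_table = pd.DataFrame(
        {
            "sample_id": np.repeat([sample_ids[j] for j in rows_j], len(grid)),
            "drug_id": np.repeat([drug_ids[i] for i in cols_i], len(grid)),
            "concentration_uM": np.tile(grid, n_pairs),
            "viability": viab.ravel(),
        }
    )

    if drug_features is None:
        drug_features = DrugFeatureSet(
            _make_fingerprints(rng, drug_ids, pathway_of, cfg.n_pathways, cfg.fingerprint_bits),
            smiles=builtin_smiles_for(drug_ids) if cfg.emit_smiles else None,
        )

    annotation = SubtypeAnnotation(
        sample_subtype=pd.Series(subtype_labels, index=sample_ids),
        drug_pathway=pd.Series(
            [f"pathway{pathway_of[d]}" for d in drug_ids], index=drug_ids
        ),
    )
    truth = SyntheticTruth(
        mu_drug=pd.Series(mu, index=drug_ids),
        sample_factor=pd.Series(sample_factor, index=sample_ids),
        causal_gene_ids=causal_ids,
        causal_weights=causal_w,
        true_log_ic50=pd.DataFrame(
            np.where(observed, true_ln_ic50, np.nan), index=sample_ids, columns=drug_ids
        ),
        subtype_effect=subtype_eff,
        hill_slope=cfg.hill_slope,
    )
    return ScreenBundle(expr, dose_table, drug_features, annotation, truth, cfg)


def generate_transfer_pair(
    config_train: SyntheticScreenConfig, config_test: SyntheticScreenConfig
) -> tuple[ScreenBundle, ScreenBundle]:
    """Two screens sharing drug-level structure but with disjoint samples.

    The drug panel (potencies, causal genes/weights, fingerprints, subtype
    effects) of the first screen is reused for the second; sample ids of the
    second are prefixed to keep the two sample sets disjoint.
    """
    if config_train.n_drugs != config_test.n_drugs:
        raise ValueError("both screens must share the drug panel size")
    if config_train.n_genes != config_test.n_genes:
        raise ValueError("both screens must share the gene panel")
    train = generate_screen(config_train)
    test = generate_screen(
        config_test, drug_truth=train.truth, drug_features=train.drug_features
    )
    rename = {s: f"T{s}" for s in test.expression.index}
    test.expression.index = [rename[s] for s in test.expression.index]
    test.dose_response["sample_id"] = test.dose_response["sample_id"].map(rename)
    test.truth.sample_factor.index = test.expression.index
    test.truth.true_log_ic50.index = test.expression.index
    test.annotation.sample_subtype.index = test.expression.index
    return train, test
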
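"""Derivation of drug-response measures from per-dosage viability data.

Four measures are produced from a dose-response curve:

* **ln-IC50** — natural log of the concentration at 50% viability under a
  fitted two-parameter log-logistic model (log-IC50 and Hill slope).
* **AUC** — trapezoidal integral of viability over log10(concentration).
* **normalized AUC** — AUC divided by the maximum possible area for the
  tested concentration range, so full survival gives 1 and full kill 0.
* **drug relevance score (DRS)** — IC50 divided by the maximum (therapeutic)
  concentration, approximating a therapeutic index.

Lower values mean higher sensitivity for all four.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import AUC, AUC_NORM, DRS, LN_IC50, MeasureTag, ResponseMatrix

__all__ = [
    "DoseResponseCurve",
    "Ic50Fit",
    "fit_ic50",
    "compute_auc",
    "drug_relevance_score",
    "curves_to_matrix",
]

logger = logging.getLogger(__name__)

# viability above 100% is common in screens; hard cap keeps fits bounded
VIABILITY_CAP = 1.2
_SLOPE_BOUNDS = (0.05, 20.0)


@dataclass
class DoseResponseCurve:
    """Viability fractions over an ascending concentration grid (uM)."""

    sample_id: str
    drug_id: str
    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise ValueError("concentrations and viability must have equal length")
        if (self.concentrations <= 0).any() or (np.diff(self.concentrations) <= 0).any():
            raise ValueError("concentrations must be positive and strictly increasing")
        if not np.isfinite(self.viability).all():
            raise ValueError("viability contains non-finite values")


@dataclass
class Ic50Fit:
    """Fitted ln-IC50 with diagnostics."""

    ln_ic50: float
    hill_slope: float
    rss: float
    extrapolated: bool


def _hill_residuals(params, lnc, viab):
    ln_ic50, h = params
    return 1.0 / (1.0 + np.exp(h * (lnc - ln_ic50))) - viab


def fit_ic50(curve: DoseResponseCurve) -> Ic50Fit:
    """Least-squares fit of the two-parameter log-logistic curve.

    The fit starts from an interpolation-based guess for the 50%-viability
    crossing and, if the residuals remain large, retries from five log-IC50
    values spanning the dose range (multi-start). When the fitted IC50 lies
    outside the tested range the result is flagged as extrapolated — a flat
    curve never silently yields NaN.
    """
    if len(curve.concentrations) < 3:
        raise ValueError("need at least 3 doses to fit an IC50")
    lnc = np.log(curve.concentrations)
    viab = np.clip(curve.viability, 0.0, VIABILITY_CAP)

    lo, hi = lnc[0] - 6.0, lnc[-1] + 6.0
    bounds = ([lo, _SLOPE_BOUNDS[0]], [hi, _SLOPE_BOUNDS[1]])

    # interpolation start: first downward crossing of 0.5
    below = np.nonzero(viab <= 0.5)[0]
    if below.size and below[0] > 0:
        k = below[0]
        v0, v1 = viab[k - 1], viab[k]
        frac = (v0 - 0.5) / (v0 - v1) if v0 != v1 else 0.5
        start = lnc[k - 1] + frac * (lnc[k] - lnc[k - 1])
    elif below.size:  # already below 0.5 at the lowest dose
        start = lnc[0] - 1.0
    else:  # never reaches 0.5
        start = lnc[-1] + 1.0
    start = np.clip(start, lo, hi)

    def solve(x0):
        return least_squares(_hill_residuals, x0, bounds=bounds, args=(lnc, viab))

    best = solve([start, 1.0])
    # multi-start fallback for curves the interpolation guess cannot handle
    if best.cost > 0.02 * len(lnc):
        for x0 in np.linspace(lnc[0], lnc[-1], 5):
            sol = solve([np.clip(x0, lo, hi), 1.0])
            if sol.cost < best.cost:
                best = sol
    ln_ic50, h = best.x
    rss = 2.0 * best.cost
    extrapolated = not (lnc[0] <= ln_ic50 <= lnc[-1])
    return Ic50Fit(float(ln_ic50), float(h), float(rss), bool(extrapolated))


def compute_auc(curve: DoseResponseCurve) -> tuple[float, float]:
    """AUC and normalized AUC of a curve.

    AUC is the trapezoidal integral of (clipped) viability over
    log10(concentration); the normalized AUC divides by the span of the
    log10 grid times the full-survival height 1.0, so it lies in
    [0, ~1.2]. Lower means more sensitive.
    """
    if len(curve.concentrations) < 2:
        raise ValueError("need at least 2 doses to compute an AUC")
    log10c = np.log10(curve.concentrations)
    viab = np.clip(curve.viability, 0.0, VIABILITY_CAP)
    auc = float(np.trapezoid(viab, log10c))
    span = log10c[-1] - log10c[0]
    return auc, auc / span


def drug_relevance_score(ln_ic50: float, max_concentration: float) -> float:
    """IC50 / maximum therapeutic concentration (unitless ratio)."""
    if max_concentration <= 0:
        raise ValueError("max_concentration must be > 0")
    return float(np.exp(ln_ic50) / max_concentration)


def curves_to_matrix(
    curves, measure: MeasureTag = LN_IC50, return_fits: bool = False
) -> ResponseMatrix | tuple[ResponseMatrix, pd.DataFrame]:
    """Assemble per-curve measure values into a samples x drugs matrix.

    Cells with no curve are missing (NaN mask). Duplicate (sample, drug)
    pairs are rejected. With ``return_fits`` the per-curve fit diagnostics
    (ln-IC50 fits only) are returned alongside.
    """
    seen: set[tuple] = set()
    records: dict[tuple, float] = {}
    fit_rows = []
    needs_fit = measure.name in (LN_IC50.name, DRS.name)
    for curve in curves:
        key = (curve.sample_id, curve.drug_id)
        if key in seen:
            raise ValueError(f"duplicate curve for sample={key[0]!r}, drug={key[1]!r}")
        seen.add(key)
        if needs_fit:
            fit = fit_ic50(curve)
            if measure.name == LN_IC50.name:
                value = fit.ln_ic50
            else:
                value = drug_relevance_score(fit.ln_ic50, curve.concentrations[-1])
            fit_rows.append(
                {
                    "sample_id": curve.sample_id,
                    "drug_id": curve.drug_id,
                    "ln_ic50": fit.ln_ic50,
                    "hill_slope": fit.hill_slope,
                    "rss": fit.rss,
                    "extrapolated": fit.extrapolated,
                }
            )
        elif measure.name == AUC.name:
            value = compute_auc(curve)[0]
        elif measure.name == AUC_NORM.name:
            value = compute_auc(curve)[1]
        else:
            raise ValueError(f"unsupported measure: {measure.name}")
        records[key] = value

    if records:
        series = pd.Series(records)
        frame = series.unstack()
        frame = frame.sort_index(axis=0).sort_index(axis=1)
    else:
        frame = pd.DataFrame(dtype=float)
    matrix = ResponseMatrix(frame, measure)
    if needs_fit and fit_rows:
        n_extr = sum(r["extrapolated"] for r in fit_rows)
        if n_extr:
            logger.warning("%d of %d fitted IC50s lie outside the tested range", n_extr, len(fit_rows))
    if return_fits:
        return matrix, pd.DataFrame(fit_rows)
    return matrix
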
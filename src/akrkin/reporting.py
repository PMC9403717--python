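"""Derived comparisons and dose-response support.

Covers isoform fold-selectivity ratios (printed at 2 significant figures,
matching the publication convention for fold statements), parabolic
composite constants k_plus/K, normalization of raw viability plates, and
4-parameter-logistic (4PL) IC50 fitting on log-dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import constants

__all__ = [
    "fold_selectivity",
    "round_sig",
    "composite_parabolic_constant",
    "DoseResponseCurve",
    "IC50Result",
    "normalize_viability",
    "fit_ic50",
    "selectivity_table",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fold_selectivity(value_a: float, value_b: float) -> float:
    """Ratio a/b rounded to 2 significant figures.

    Both values must be positive and in the same units; used e.g. to compare
    a compound's K3 across isoforms or IC50 across cell lines.
    """
    if not (value_a > 0 and value_b > 0):
        raise ValueError("fold selectivity requires two positive values")
    return round_sig(value_a / value_b, 2)


def composite_parabolic_constant(k_plus: float, K: float) -> float:
    """Composite second-order inactivation constant k_plus / K (M^-2 s^-1)."""
    if k_plus < 0:
        raise ValueError("k_plus must be non-negative")
    if not K > 0:
        raise ValueError("K must be positive")
    return k_plus / K


# ---------------------------------------------------------------------------
# viability dose-response


@dataclass
class DoseResponseCurve:
    """Normalized viability (fraction of untreated control) per dose (M)."""

    doses: np.ndarray
    response: np.ndarray
    compound_id: Optional[str] = None
    cell_line: Optional[str] = None
    n_replicates: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.doses.shape != self.response.shape or self.doses.ndim != 1:
            raise ValueError("doses and response must be equal-length 1-D arrays")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("normalized response must be finite")


@dataclass
class IC50Result:
    """4PL fit summary; the 95% CI is asymptotic on log(IC50)."""

    ic50: float
    hill: float
    top: float
    bottom: float
    ci95: Tuple[float, float]
    converged: bool
    ci_method: str = "asymptotic"
    rss: float = math.nan


def normalize_viability(
    raw: Mapping[float, Sequence[float]],
    background,
    control: float,
    *,
    compound_id: Optional[str] = None,
    cell_line: Optional[str] = None,
) -> DoseResponseCurve:
    """Normalize a raw absorbance plate to fractions of untreated control.

    Per dose: replicate absorbances are averaged first, then the compound
    blank (well with substance, no cells) is subtracted, and the result is
    divided by the background-corrected untreated-control absorbance.
    ``background`` may be a scalar or a per-dose mapping.
    """
    bg_of = background.get if isinstance(background, Mapping) else (lambda d, _=None: background)
    bg_ctrl = (float(np.mean(list(background.values())))
               if isinstance(background, Mapping) else background)
    denom = control - bg_ctrl
    if denom <= 0:
        raise ValueError("untreated control does not exceed background; "
                         "normalization is not viable")
    doses = sorted(raw)
    vals, nrep = [], []
    for d in doses:
        reps = np.asarray(raw[d], dtype=float)
        vals.append((float(np.mean(reps)) - bg_of(d)) / denom)
        nrep.append(len(reps))
    return DoseResponseCurve(np.array(doses), np.array(vals),
                             compound_id=compound_id, cell_line=cell_line,
                             n_replicates=nrep)


def _fourpl(doses: np.ndarray, ic50: float, hill: float, top: float, bottom: float):
    with np.errstate(divide="ignore"):
        ratio = np.where(doses > 0, (doses / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_ic50(curve: DoseResponseCurve) -> IC50Result:
    """Fit a monotone-decreasing 4PL on log-dose and return the IC50.

    y(d) = bottom + (top - bottom) / (1 + (d/IC50)^hill) with hill > 0 and
    top >= bottom enforced by the parameterisation.  The 95% confidence
    interval is asymptotic on ln(IC50).
    """
    d, y = curve.doses, curve.response
    nz = d[d > 0]
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses for a 4PL fit")
    if float(np.max(y) - np.min(y)) < 0.1:
        raise RuntimeError(
            "no dose-response transition in the tested range; widen the dose "
            "range or increase the top concentration before fitting")

    # theta = [ln ic50, ln hill, bottom, ln span]; top = bottom + span
    def unpack(theta):
        ic50 = math.exp(theta[0])
        hill = math.exp(theta[1])
        bottom = theta[2]
        top = bottom + math.exp(theta[3])
        return ic50, hill, top, bottom

    def resid(theta):
        return _fourpl(d, *unpack(theta)) - y

    half = (np.max(y) + np.min(y)) / 2.0
    ic50_guess = float(nz[np.argmin(np.abs(y[d > 0] - half))]) if len(nz) else 1e-5
    theta0 = np.array([
        math.log(ic50_guess),
        0.0,
        float(np.min(y)),
        math.log(max(float(np.max(y) - np.min(y)), 1e-3)),
    ])
    sol = least_squares(resid, theta0, method="trf", xtol=1e-14, ftol=1e-14)
    ic50, hill, top, bottom = unpack(sol.x)
    n, p = len(y), 4
    sigma2 = 2.0 * sol.cost / max(n - p, 1)
    try:
        cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        s_log_ic50 = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        s_log_ic50 = math.nan
    if math.isfinite(s_log_ic50):
        ci = (ic50 * math.exp(-1.96 * s_log_ic50), ic50 * math.exp(1.96 * s_log_ic50))
    else:
        ci = (math.nan, math.nan)
    return IC50Result(ic50=ic50, hill=hill, top=top, bottom=bottom, ci95=ci,
                      converged=bool(sol.status > 0), rss=float(2.0 * sol.cost))


# ---------------------------------------------------------------------------
# published-constant summaries


def selectivity_table(reference: str = "AKR1C1") -> pd.DataFrame:
    """Fold-selectivity of each compound's constants versus a reference
    isoform, computed from the published inhibition constants.

    Folds are K(other)/K(reference) per branch (a fold > 1 means less
    efficient inhibition of the other isoform), rounded to 2 s.f.
    """
    rows = []
    for cpd, per_enzyme in constants.INHIBITION_CONSTANTS.items():
        ref = per_enzyme.get(reference, {})
        for enzyme, vals in per_enzyme.items():
            row = {"compound": cpd, "enzyme": enzyme}
            for key in ("K2", "k_plus2", "K3", "k_plus3", "composite3"):
                row[key] = vals.get(key)
            for key in ("K2", "K3"):
                v, r = vals.get(key), ref.get(key)
                if v and r and enzyme != reference:
                    row[f"fold_{key}_vs_{reference}"] = fold_selectivity(v, r)
            rows.append(row)
    return pd.DataFrame(rows)
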
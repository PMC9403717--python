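"""Global weighted least-squares estimation of the kinetic scheme's
parameters from progress-curve sets.

The fit is global in two senses: a single parameter vector is shared by all
curves (across inhibitor concentrations, replicates and experimental data
sets), and the optimiser is multistarted (Latin-hypercube in log-parameter
space around heuristic seeds) because the reversible constant K and the
irreversible rate k_plus of a branch are strongly correlated.  Parameters
are optimised on a natural-log scale, which enforces positivity and makes
the reported relative standard errors directly comparable across decades.

A two-stage protocol mirrors how the published constants are organised:
substrate/coenzyme constants come from inhibitor-free controls
(:func:`fit_substrate_constants`) and are then held fixed while the
inhibition constants are estimated (:func:`fit_inhibition`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .mechanism import AssayConditions, MechanismParams
from .simulate import CurveSet, absorbance_from_concentration, simulate_nadh
from .synthetic import AssayDesign

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_substrate_constants",
    "fit_inhibition",
    "select_variant",
    "NonIdentifiableError",
]

_FREE_NAMES = ("K2", "k_plus2", "K3", "k_plus3", "composite2", "composite3")


class NonIdentifiableError(RuntimeError):
    """The data cannot constrain the requested parameters."""


@dataclass(frozen=True)
class FitOptions:
    """Optimiser configuration.

    ``n_starts`` Latin-hypercube multistarts are drawn within
    ``spread_decades`` decades around the heuristic initial guesses; the
    heuristic point itself is always start 0.
    """

    n_starts: int = 8
    spread_decades: float = 2.0
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-12
    xtol: float = 1e-12
    ftol: float = 1e-12
    max_nfev: Optional[int] = None


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one global fit.

    ``params``/``se`` are on the natural (linear) scale; ``cov_log`` is the
    covariance of the natural-log parameters (asymptotic, from the Jacobian
    at the optimum).  ``per_curve_rss`` supports residual diagnostics.
    """

    params: Dict[str, float]
    se: Dict[str, float]
    fixed: Dict[str, float]
    variant: str
    rss: float
    n_obs: int
    converged: bool
    n_starts: int
    seed: int
    free_names: tuple
    cov_log: Optional[np.ndarray] = None
    per_curve_rss: Dict[str, float] = field(default_factory=dict)
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def rel_se_log(self, name: str) -> float:
        """Standard deviation of ln(parameter) — approx. relative SE."""
        i = self.free_names.index(name)
        if self.cov_log is None:
            return math.nan
        return math.sqrt(max(self.cov_log[i, i], 0.0))

    def summary(self) -> str:
        lines = [f"variant={self.variant}  rss={self.rss:.6g}  n={self.n_obs}  "
                 f"converged={self.converged}"]
        for k in self.free_names:
            lines.append(f"  {k} = {self.params[k]:.4g} +/- {self.se.get(k, math.nan):.2g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# residual machinery


class _CurvePlan:
    """Precomputed mapping from a CurveSet to stacked ODE evaluations.

    Curves are grouped by identical time grid; within a group each unique
    inhibitor concentration is simulated once and shared by all replicates
    and data sets at that concentration.
    """

    def __init__(self, curves: CurveSet, design: AssayDesign):
        self.design = design
        groups: dict = {}
        for c in curves:
            key = c.times.tobytes()
            groups.setdefault(key, {"grid": c.times, "concs": [], "curves": []})
            groups[key]["curves"].append(c)
        self.groups = []
        self.n_obs = 0
        for g in groups.values():
            # canonical curve order makes the fit invariant to input order
            g["curves"].sort(key=lambda c: (c.meta.inhibitor_conc_M,
                                            c.meta.dataset_id,
                                            c.meta.replicate,
                                            c.meta.curve_id))
            concs = sorted({c.meta.inhibitor_conc_M for c in g["curves"]})
            idx = {ci: j for j, ci in enumerate(concs)}
            conds = [design.conditions(ci) for ci in concs]
            obs = [(idx[c.meta.inhibitor_conc_M], c.absorbance) for c in g["curves"]]
            self.groups.append({"grid": g["grid"], "conds": conds, "obs": obs,
                                "curves": g["curves"]})
            self.n_obs += sum(len(c.times) for c in g["curves"])

    def residuals(self, params: MechanismParams, opts: FitOptions) -> np.ndarray:
        out = []
        for g in self.groups:
            nadh = simulate_nadh(params, g["conds"], g["grid"],
                                 rtol=opts.rtol, atol=opts.atol)
            model = absorbance_from_concentration(
                nadh, self.design.epsilon, self.design.path_length)
            for j, ab in g["obs"]:
                out.append(model[j] - ab)
        return np.concatenate(out)

    def per_curve_rss(self, params: MechanismParams, opts: FitOptions) -> Dict[str, float]:
        out = {}
        for g in self.groups:
            nadh = simulate_nadh(params, g["conds"], g["grid"],
                                 rtol=opts.rtol, atol=opts.atol)
            model = absorbance_from_concentration(
                nadh, self.design.epsilon, self.design.path_length)
            for (j, ab), c in zip(g["obs"], g["curves"]):
                out[c.meta.curve_id] = float(np.sum((model[j] - ab) ** 2))
        return out


def _resolve_design(curves: CurveSet, design: Optional[AssayDesign]) -> AssayDesign:
    design = design or curves.attrs.get("design")
    if design is None:
        raise ValueError("an AssayDesign is required (pass design= or use a "
                         "CurveSet generated by this package)")
    return design


def _multistart(theta0: np.ndarray, opts: FitOptions) -> np.ndarray:
    """Start points in log-space: the heuristic plus LHS jitter around it."""
    if opts.n_starts <= 1:
        return theta0[None, :]
    sampler = qmc.LatinHypercube(d=len(theta0), seed=opts.seed)
    u = sampler.random(opts.n_starts - 1)  # in [0, 1)
    spread = opts.spread_decades * math.log(10.0)
    jitter = (2.0 * u - 1.0) * spread
    return np.vstack([theta0, theta0 + jitter])


def _run_multistart(resid_fn, theta0: np.ndarray, opts: FitOptions):
    best = None
    for start in _multistart(theta0, opts):
        try:
            sol = least_squares(resid_fn, start, method="trf",
                                xtol=opts.xtol, ftol=opts.ftol, gtol=1e-12,
                                max_nfev=opts.max_nfev)
        except (ValueError, RuntimeError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise NonIdentifiableError("all multistarts failed to converge")
    return best


def _covariance_log(sol, n_obs: int) -> Optional[np.ndarray]:
    p = len(sol.x)
    dof = max(n_obs - p, 1)
    sigma2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        return None
    return cov


def _condition_number(sol) -> float:
    j = sol.jac
    norms = np.linalg.norm(j, axis=0)
    norms[norms == 0] = 1.0
    js = j / norms
    return float(np.linalg.cond(js.T @ js))


# ---------------------------------------------------------------------------
# stage 1: substrate constants from inhibitor-free controls


def fit_substrate_constants(
    control_curves: CurveSet,
    *,
    design: Optional[AssayDesign] = None,
    K_NAD: float = 0.16e-3,
    K_NADH: float = 0.61e-3,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Estimate the enantiomer specificity constants k_spec1 >= k_spec2 from
    inhibitor-free progress curves, with the coenzyme dissociation constants
    held fixed (defaults are the published shared values).

    The fast/slow labelling is enforced by swapping after the fit, so the
    returned k_spec1 always belongs to the faster enantiomer.
    """
    opts = options or FitOptions()
    design = _resolve_design(control_curves, design)
    ctrl = [c for c in control_curves if c.meta.inhibitor_conc_M == 0.0]
    if not ctrl:
        raise ValueError("no inhibitor-free (0 M) control curves in the set")
    span = max(float(np.ptp(c.absorbance)) for c in ctrl)
    if span < 1e-4:
        raise NonIdentifiableError(
            "control curves are flat (absorbance span < 1e-4 AU); "
            "specificity constants are not identifiable")
    plan = _CurvePlan(CurveSet(ctrl), design)

    def make_params(theta):
        k1, k2 = np.exp(theta)
        return MechanismParams(K_NAD=K_NAD, K_NADH=K_NADH,
                               k_spec1=k1, k_spec2=k2, variant="full")

    def resid(theta):
        return plan.residuals(make_params(theta), opts)

    # heuristic: fast phase from time-to-half of the final signal
    c0 = ctrl[0]
    cond0 = design.conditions(0.0)
    f = (cond0.NAD0 / K_NAD) / (1.0 + cond0.NAD0 / K_NAD)
    final = float(np.max(c0.absorbance))
    t_half_idx = int(np.searchsorted(c0.absorbance, final / 2.0))
    t_half = max(float(c0.times[min(t_half_idx, len(c0.times) - 1)]), design.interval)
    lam1 = math.log(2.0) / t_half
    k1_guess = lam1 / (cond0.E_total * f)
    theta0 = np.log([k1_guess, k1_guess / 10.0])

    sol = _run_multistart(resid, theta0, opts)
    k1, k2 = np.exp(sol.x)
    cov = _covariance_log(sol, plan.n_obs)
    se = np.sqrt(np.clip(np.diag(cov), 0, None)) if cov is not None else [math.nan] * 2
    names = ("k_spec1", "k_spec2")
    ests = [k1, k2]
    ses = [k1 * se[0], k2 * se[1]]
    if ests[0] < ests[1]:  # label swap: k_spec1 is the fast enantiomer
        ests = ests[::-1]
        ses = ses[::-1]
        if cov is not None:
            cov = cov[::-1, ::-1]
    best_params = make_params(np.log(ests))
    return FitResult(
        params=dict(zip(names, ests)),
        se=dict(zip(names, ses)),
        fixed={"K_NAD": K_NAD, "K_NADH": K_NADH},
        variant="full",
        rss=float(2.0 * sol.cost),
        n_obs=plan.n_obs,
        converged=bool(sol.status > 0),
        n_starts=opts.n_starts,
        seed=opts.seed,
        free_names=names,
        cov_log=cov,
        per_curve_rss=plan.per_curve_rss(best_params, opts),
        diagnostics={"condition_number": _condition_number(sol)},
    )


# ---------------------------------------------------------------------------
# stage 2: inhibition constants


def _validate_free(variant: str, free_names: Sequence[str]) -> None:
    bad = [n for n in free_names if n not in _FREE_NAMES]
    if bad:
        raise ValueError(f"unknown free parameters {bad}; valid: {_FREE_NAMES}")
    if not free_names:
        raise ValueError("at least one free parameter is required")
    if variant == "reversible_only" and any(n.startswith(("k_plus", "composite"))
                                            for n in free_names):
        raise ValueError("variant 'reversible_only' frees only K2/K3")
    if variant == "parabolic":
        if not any(n.startswith("composite") for n in free_names):
            raise ValueError("variant 'parabolic' requires a free composite constant")
    if variant == "full" and any(n.startswith("composite") for n in free_names):
        raise ValueError("composite constants belong to variant 'parabolic'")


def _heuristic_guess(name: str, concs: np.ndarray, duration: float) -> float:
    nz = concs[concs > 0]
    gmean = float(np.exp(np.mean(np.log(nz))))
    i_min = float(np.min(nz))
    if name in ("K2", "K3"):
        return gmean
    if name.startswith("k_plus"):
        return 1.0 / (i_min * duration)
    return 1.0 / (i_min**2 * duration)  # composite


def fit_inhibition(
    curves: CurveSet,
    shared: Dict[str, float],
    free: Dict[str, Optional[float]],
    *,
    variant: str = "full",
    design: Optional[AssayDesign] = None,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Globally fit the inhibition constants of the scheme to a CurveSet.

    Parameters
    ----------
    shared
        Fixed stage-1 constants: K_NAD, K_NADH, k_spec1, k_spec2.
    free
        Mapping of free parameter names (K2, k_plus2, K3, k_plus3,
        composite2, composite3) to initial guesses; ``None`` requests a
        data-driven heuristic guess.
    variant
        Model variant the free set must be consistent with.

    The objective is the unweighted sum of squared absorbance residuals over
    every curve in the set — replicates and experimental data sets enter
    jointly with shared parameters.
    """
    opts = options or FitOptions()
    design = _resolve_design(curves, design)
    free_names = tuple(free.keys())
    _validate_free(variant, free_names)
    concs = curves.concentrations()
    if len(concs) < 3 or 0.0 not in concs:
        raise ValueError(
            "inhibition fitting needs >= 3 distinct inhibitor concentrations "
            "including a 0 control; inhibition parameters are otherwise "
            "unidentifiable")
    plan = _CurvePlan(curves, design)

    def make_params(theta):
        vals = dict(zip(free_names, np.exp(theta)))
        kw = dict(K_NAD=shared["K_NAD"], K_NADH=shared["K_NADH"],
                  k_spec1=shared["k_spec1"], k_spec2=shared["k_spec2"],
                  variant=variant)
        for n in _FREE_NAMES:
            if n in vals:
                kw[n] = vals[n]
        return MechanismParams(**kw)

    def resid(theta):
        return plan.residuals(make_params(theta), opts)

    theta0 = np.log([
        free[n] if free[n] is not None
        else _heuristic_guess(n, concs, design.duration)
        for n in free_names
    ])
    sol = _run_multistart(resid, theta0, opts)
    est = np.exp(sol.x)
    cov = _covariance_log(sol, plan.n_obs)
    se = (np.sqrt(np.clip(np.diag(cov), 0, None)) * est
          if cov is not None else np.full(len(est), math.nan))
    best_params = make_params(sol.x)
    return FitResult(
        params=dict(zip(free_names, est)),
        se=dict(zip(free_names, se)),
        fixed=dict(shared),
        variant=variant,
        rss=float(2.0 * sol.cost),
        n_obs=plan.n_obs,
        converged=bool(sol.status > 0),
        n_starts=opts.n_starts,
        seed=opts.seed,
        free_names=free_names,
        cov_log=cov,
        per_curve_rss=plan.per_curve_rss(best_params, opts),
        diagnostics={"condition_number": _condition_number(sol)},
    )


# ---------------------------------------------------------------------------
# variant selection


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _branch_names(branch: str):
    return ("K2", "k_plus2", "composite2") if branch == "nad" else ("K3", "k_plus3", "composite3")


def select_variant(
    curves: CurveSet,
    shared: Dict[str, float],
    *,
    branches: Sequence[str] = ("nadh",),
    design: Optional[AssayDesign] = None,
    options: Optional[FitOptions] = None,
) -> dict:
    """Fit candidate model variants and recommend one.

    Candidates: ``reversible_only`` (K only), ``full`` (K and k_plus) and
    ``parabolic`` (composite k_plus/K), over the requested holoenzyme
    branches ("nad" = E.NAD.I, "nadh" = E.NADH.I).

    Recommendation rules: *parabolic* when the full fit leaves K and k_plus
    of a branch jointly unidentifiable (both relative SEs > 100%) while
    their ratio is stable (relative SE of the ratio < 25%) and the parabolic
    fit is at least as parsimonious as the reversible one; *reversible_only*
    when no k_plus estimate is significantly above zero or the reversible
    fit has the best small-sample information criterion; otherwise *full*.

    Returns a dict with per-variant FitResults, AICc scores, Jacobian
    condition numbers and the recommendation.
    """
    opts = options or FitOptions()
    design = _resolve_design(curves, design)
    free_by_variant = {
        "reversible_only": [b[0] for b in map(_branch_names, branches)],
        "full": [n for b in map(_branch_names, branches) for n in b[:2]],
        "parabolic": [b[2] for b in map(_branch_names, branches)],
    }
    fits: Dict[str, FitResult] = {}
    scores: Dict[str, float] = {}
    for variant, names in free_by_variant.items():
        fr = fit_inhibition(curves, shared, {n: None for n in names},
                            variant=variant, design=design, options=opts)
        fits[variant] = fr
        scores[variant] = _aicc(fr.rss, fr.n_obs, len(names))

    full = fits["full"]
    parabolic_signature = False
    ratio_rel_se = math.nan
    for branch in branches:
        kname, pname, _ = _branch_names(branch)
        if full.cov_log is None:
            continue
        i, j = full.free_names.index(kname), full.free_names.index(pname)
        s_k = math.sqrt(max(full.cov_log[i, i], 0.0))
        s_p = math.sqrt(max(full.cov_log[j, j], 0.0))
        var_ratio = full.cov_log[i, i] + full.cov_log[j, j] - 2 * full.cov_log[i, j]
        ratio_rel_se = math.sqrt(max(var_ratio, 0.0))
        if s_k > 1.0 and s_p > 1.0 and ratio_rel_se < 0.25:
            parabolic_signature = True

    kplus_significant = False
    for branch in branches:
        _, pname, _ = _branch_names(branch)
        est = full.params[pname]
        se = full.se.get(pname, math.nan)
        if np.isfinite(se) and est - 1.96 * se > 0:
            kplus_significant = True

    if parabolic_signature and scores["parabolic"] <= scores["reversible_only"]:
        recommendation = "parabolic"
    elif (not kplus_significant) or scores["reversible_only"] == min(scores.values()):
        recommendation = "reversible_only"
    else:
        recommendation = "full"

    return {
        "recommendation": recommendation,
        "fits": fits,
        "aicc": scores,
        "condition_numbers": {v: f.diagnostics.get("condition_number", math.nan)
                              for v, f in fits.items()},
        "parabolic_signature": parabolic_signature,
        "ratio_rel_se": ratio_rel_se,
        "kplus_significant": kplus_significant,
    }
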
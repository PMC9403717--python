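"""Reusable simulation studies: parameter-recovery Monte Carlo runs and the
oracle-equivalence sweep.

Each study regenerates its synthetic data from the published assay design
and parameter sets, runs the estimator, and returns plain dictionaries so
drivers can serialise them.  Seeds are explicit everywhere.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from . import constants
from .fitting import FitOptions, fit_inhibition, fit_substrate_constants, select_variant
from .mechanism import MechanismParams
from .published import published_params
from .simulate import mass_action_reference, simulate_progress_curve
from .synthetic import NoiseModel, default_assay_design, generate_curveset

NOISE_SD_DEFAULT = 0.002  # AU, plate-reader read noise assumed by the studies


def _mc_opts(seed: int, n_starts: int = 4) -> FitOptions:
    return FitOptions(n_starts=n_starts, seed=seed, xtol=1e-10, ftol=1e-10)


def substrate_recovery_study(
    *, seed: int = 0, n_noisy: int = 20, noise_sd: float = NOISE_SD_DEFAULT,
) -> Dict:
    """Recover AKR1C1 enantiomer specificity constants from inhibitor-free
    control curves: once noiselessly, then over ``n_noisy`` noise seeds."""
    shared = constants.SHARED_CONSTANTS["AKR1C1"]
    truth = MechanismParams(**shared)
    design = default_assay_design("AKR1C1")
    clean = generate_curveset(truth, design, NoiseModel(sd=0.0, seed=seed))
    fr0 = fit_substrate_constants(clean.controls(), options=_mc_opts(seed, 2))
    noisy_k1 = []
    for j in range(n_noisy):
        cs = generate_curveset(truth, design,
                               NoiseModel(sd=noise_sd, seed=seed + 1000 + j))
        fr = fit_substrate_constants(cs.controls(), options=_mc_opts(seed, 2))
        noisy_k1.append(fr.params["k_spec1"])
    return {
        "truth_k_spec1": shared["k_spec1"],
        "truth_k_spec2": shared["k_spec2"],
        "noiseless_k_spec1": fr0.params["k_spec1"],
        "noiseless_k_spec2": fr0.params["k_spec2"],
        "noisy_k_spec1": noisy_k1,
        "noisy_median_k_spec1": float(np.median(noisy_k1)),
        "n_obs": fr0.n_obs,
    }


def inhibition_recovery_study(
    compound: int,
    enzyme_id: str,
    free_names: Sequence[str],
    *, seed: int = 0, n_seeds: int = 10, noise_sd: float = NOISE_SD_DEFAULT,
    n_starts: int = 4,
) -> Dict:
    """Monte-Carlo recovery of inhibition constants for one published
    compound/isoform set (7 concentrations + control, triplicate wells)."""
    truth = published_params(compound, enzyme_id)
    shared = dict(constants.SHARED_CONSTANTS[enzyme_id])
    design = default_assay_design(enzyme_id)
    estimates: Dict[str, list] = {n: [] for n in free_names}
    for j in range(n_seeds):
        cs = generate_curveset(truth, design,
                               NoiseModel(sd=noise_sd, seed=seed + 2000 + j))
        fr = fit_inhibition(cs, shared, {n: None for n in free_names},
                            variant=truth.variant,
                            options=_mc_opts(seed + j, n_starts))
        for n in free_names:
            estimates[n].append(fr.params[n])
    out = {"compound": compound, "enzyme": enzyme_id, "n_seeds": n_seeds,
           "n_curves": len(design.inhibitor_concs) * design.replicates}
    for n in free_names:
        out[f"truth_{n}"] = getattr(truth, n)
        out[f"estimates_{n}"] = estimates[n]
        out[f"median_{n}"] = float(np.median(estimates[n]))
    return out


def parabolic_classification_study(
    *, seed: int = 0, n_seeds: int = 10, noise_sd: float = NOISE_SD_DEFAULT,
) -> Dict:
    """Classify and recover pure second-order inactivation (compound-8-like
    behaviour on AKR1C3): data generated with only a composite k_plus3/K3."""
    truth = published_params(8, "AKR1C3")  # composite3 = 1.97e6 M^-2 s^-1
    shared = dict(constants.SHARED_CONSTANTS["AKR1C3"])
    design = default_assay_design("AKR1C3")
    recommendations, composites = [], []
    for j in range(n_seeds):
        cs = generate_curveset(truth, design,
                               NoiseModel(sd=noise_sd, seed=seed + 3000 + j))
        sel = select_variant(cs, shared, branches=("nadh",),
                             options=_mc_opts(seed + j, 2))
        recommendations.append(sel["recommendation"])
        composites.append(sel["fits"]["parabolic"].params["composite3"])
    return {
        "truth_composite3": truth.composite3,
        "recommendations": recommendations,
        "n_parabolic": sum(r == "parabolic" for r in recommendations),
        "composites": composites,
        "median_composite3": float(np.median(composites)),
        "n_seeds": n_seeds,
    }


def oracle_equivalence_sweep(
    *, seed: int = 0, n_points: int = 30, k_off: float = 1e3,
) -> Dict:
    """Randomized comparison of the rapid-equilibrium simulator against the
    full mass-action integrator: published parameter sets jittered by up to
    x2 per constant, at a random concentration of the standard design."""
    rng = np.random.default_rng(seed)
    combos = [(cpd, enz) for cpd, per in constants.INHIBITION_CONSTANTS.items()
              for enz in per]
    rel_errors, details = [], []
    jitter_fields = ("K2", "K3", "k_plus2", "k_plus3", "composite2", "composite3")
    for _ in range(n_points):
        cpd, enz = combos[rng.integers(len(combos))]
        base = published_params(cpd, enz)
        changes = {}
        for f in jitter_fields:
            v = getattr(base, f)
            if v:
                changes[f] = v * 10 ** rng.uniform(-0.3, 0.3)
        params = base.evolve(**changes)
        design = default_assay_design(enz)
        i_conc = design.inhibitor_concs[rng.integers(len(design.inhibitor_concs))]
        cond = design.conditions(i_conc)
        grid = design.time_grid()
        red = simulate_progress_curve(params, cond, grid)
        ora = mass_action_reference(params, cond, grid, k_off=k_off)
        err = abs(red.nadh[-1] - ora.nadh[-1]) / max(ora.nadh[-1], 1e-30)
        rel_errors.append(float(err))
        details.append({"compound": cpd, "enzyme": enz, "i_conc": i_conc,
                        "rel_error": float(err)})
    return {"rel_errors": rel_errors, "max_rel_error": float(max(rel_errors)),
            "details": details, "k_off": k_off, "n_points": n_points}
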
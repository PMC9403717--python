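"""Synthetic plate-reader data: assay designs mirroring the AKR1C1-3
spectrophotometric inhibition assay and a noise model for generating
CurveSets with known ground truth.

The design constants reproduce the published assay: 300 uL reactions with
2.3 mM NAD+, racemic 1-acenaphthenol at 90/180/250 uM and enzyme at
0.11/0.16/1.5 uM for AKR1C1/2/3, seven inhibitor concentrations spanning
1-200 uM plus an inhibitor-free control, 3 h of reads at 340 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import constants
from .mechanism import AssayConditions, MechanismParams
from .simulate import CurveMeta, CurveSet, ProgressCurve, simulate_nadh, absorbance_from_concentration

__all__ = ["AssayDesign", "NoiseModel", "default_assay_design", "generate_curveset"]


def _default_concs() -> tuple:
    # 7 log-spaced inhibitor concentrations in 1-200 uM plus a 0 control
    return (0.0,) + tuple(np.geomspace(1e-6, 200e-6, 7))


@dataclass(frozen=True)
class AssayDesign:
    """One enzyme's plate layout: which wells exist and at what conditions.

    ``inhibitor_concs`` are molar and must include a 0 control;
    ``n_datasets`` > 1 expresses independent experimental runs that are fit
    jointly with shared parameters.
    """

    enzyme_id: str
    S_total: float
    E_total: float
    NAD0: float = constants.NAD0_DEFAULT
    inhibitor_concs: tuple = field(default_factory=_default_concs)
    replicates: int = 3
    n_datasets: int = 1
    duration: float = 10800.0
    interval: float = 60.0
    epsilon: float = constants.EPSILON_NADH_340
    path_length: float = 0.9

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.inhibitor_concs):
            raise ValueError("inhibitor concentrations must be non-negative")
        if 0.0 not in self.inhibitor_concs:
            raise ValueError("inhibitor concentration list must contain a 0 control")
        if self.replicates < 1 or self.n_datasets < 1:
            raise ValueError("replicates and n_datasets must be >= 1")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.interval))
        return np.linspace(0.0, n * self.interval, n + 1)

    def conditions(self, i_conc: float) -> AssayConditions:
        return AssayConditions(
            E_total=self.E_total, NAD0=self.NAD0, S_total=self.S_total,
            I_conc=i_conc, duration=self.duration, epsilon=self.epsilon,
            path_length=self.path_length,
        )

    def evolve(self, **changes) -> "AssayDesign":
        return replace(self, **changes)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian absorbance noise with optional linear baseline drift.

    ``sd`` is in AU (default 0.002, a typical plate-reader read noise);
    ``drift`` in AU per hour.  The seed is mandatory so every generated data
    set is reproducible.
    """

    sd: float = 0.002
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_assay_design(enzyme_id: str) -> AssayDesign:
    """Per-isoform defaults of the published assay (substrate, enzyme, NAD+)."""
    if enzyme_id not in constants.ASSAY_DEFAULTS:
        raise ValueError(
            f"unknown enzyme id {enzyme_id!r}; valid ids: {sorted(constants.ASSAY_DEFAULTS)}"
        )
    d = constants.ASSAY_DEFAULTS[enzyme_id]
    return AssayDesign(enzyme_id=enzyme_id, S_total=d["S_total"], E_total=d["E_total"])


def generate_curveset(
    params: MechanismParams,
    design: AssayDesign,
    noise: NoiseModel,
    *,
    compound_id: Optional[str] = None,
) -> CurveSet:
    """Simulate one plate: a ProgressCurve per (dataset, concentration,
    replicate) with noise applied to absorbance only.

    The noiseless model curve per concentration is computed once (replicates
    share it); noise draws are independent per well.  The returned CurveSet
    records the generating parameters, design and seed in ``attrs`` for
    recovery studies.
    """
    rng = np.random.default_rng(noise.seed)
    grid = design.time_grid()
    concs = list(design.inhibitor_concs)
    conds = [design.conditions(c) for c in concs]
    nadh = simulate_nadh(params, conds, grid)
    baseline = noise.drift * grid / 3600.0
    curves = []
    for ds in range(1, design.n_datasets + 1):
        for j, c in enumerate(concs):
            clean = absorbance_from_concentration(nadh[j], design.epsilon, design.path_length)
            for rep in range(1, design.replicates + 1):
                ab = clean + baseline
                if noise.sd > 0:
                    ab = ab + rng.normal(0.0, noise.sd, size=len(grid))
                meta = CurveMeta(
                    curve_id=f"{design.enzyme_id}_i{j:02d}_d{ds}_r{rep}",
                    inhibitor_conc_M=c,
                    replicate=rep,
                    dataset_id=f"ds{ds}",
                    enzyme_id=design.enzyme_id,
                    compound_id=compound_id,
                )
                curves.append(ProgressCurve(times=grid, absorbance=np.array(ab),
                                            nadh=nadh[j].copy(), meta=meta))
    attrs = {
        "seed": noise.seed,
        "noise_sd": noise.sd,
        "drift": noise.drift,
        "enzyme_id": design.enzyme_id,
        "design": design,
        "truth": params,
    }
    return CurveSet(curves, attrs)
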
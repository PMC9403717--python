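"""Kinetic scheme for oxidation of racemic 1-acenaphthenol by AKR1C1-3 and
its inhibition by two-step-binding metalloinhibitors.

The enzyme cycles through rapid binding equilibria — apoenzyme E, holoenzymes
E.NAD and E.NADH, and their reversible inhibitor complexes E.NAD.I and
E.NADH.I — while three slow processes drive the observable kinetics:

* oxidation of the fast substrate enantiomer A by E.NAD (rate constant
  ``k_spec1``, a second-order specificity constant),
* oxidation of the slow enantiomer B (``k_spec2``),
* irreversible inactivation by association of a second inhibitor molecule
  with E.NAD.I or E.NADH.I (second-order rate constants ``k_plus2`` and
  ``k_plus3``).

Fast steps are collapsed into an algebraic partition of the active enzyme
(rapid-equilibrium approximation), so the only dynamical variables are the
two enantiomer concentrations and the inactivated-enzyme pool.  Binding of
inhibitor to the apoenzyme is excluded (its affinity is much lower), and
coenzyme sequestration by the enzyme is neglected in the NAD+/NADH mass
balance (enzyme is <= 1.5 uM against 2.3 mM NAD+).

The *parabolic* variant covers inhibitors for which the reversible constant
K and the irreversible rate k_plus of a branch are not separately
identifiable: only the composite k_plus/K (M^-2 s^-1) enters the model and
the inactivation rate grows with the square of inhibitor concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MechanismParams",
    "AssayConditions",
    "EnzymeSpeciesPartition",
    "SlowState",
    "SlowRates",
    "partition_active_enzyme",
    "slow_rhs",
    "InvalidParameterError",
]

VARIANTS = ("reversible_only", "full", "parabolic")


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates the scheme's constraints."""


def _require_nonneg(name: str, value) -> None:
    if value is not None and value < 0:
        raise InvalidParameterError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class MechanismParams:
    """All rate/equilibrium constants of the scheme for one enzyme-compound
    pair.

    ``K2``/``K3`` are dissociation constants of the first inhibitor molecule
    from E.NAD.I / E.NADH.I (M); ``None`` means "not determined" — that
    reversible branch is absent from the model (K -> infinity), which is
    distinct from K = 0 (an error).  ``k_plus2``/``k_plus3`` (M^-1 s^-1) may
    be 0 (no irreversible step).  ``composite2``/``composite3`` (M^-2 s^-1)
    replace the (K, k_plus) pair of a branch under the parabolic variant.
    """

    K_NAD: float
    K_NADH: float
    k_spec1: float
    k_spec2: float
    K2: Optional[float] = None
    K3: Optional[float] = None
    k_plus2: float = 0.0
    k_plus3: float = 0.0
    composite2: Optional[float] = None
    composite3: Optional[float] = None
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidParameterError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        for name in ("K_NAD", "K_NADH"):
            v = getattr(self, name)
            if not v > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v!r}")
        for name in ("k_spec1", "k_spec2", "k_plus2", "k_plus3"):
            _require_nonneg(name, getattr(self, name))
        for name in ("K2", "K3"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidParameterError(
                    f"{name} must be > 0 or None for 'not determined', got {v!r}"
                )
        for name in ("composite2", "composite3"):
            _require_nonneg(name, getattr(self, name))
        if self.variant == "reversible_only" and (self.k_plus2 != 0 or self.k_plus3 != 0):
            raise InvalidParameterError(
                "variant 'reversible_only' requires k_plus2 = k_plus3 = 0"
            )
        if self.variant == "parabolic":
            if self.composite2 is None and self.composite3 is None:
                raise InvalidParameterError(
                    "variant 'parabolic' requires at least one composite constant"
                )
            if self.composite2 is not None and (self.K2 is not None or self.k_plus2 != 0):
                raise InvalidParameterError(
                    "composite2 replaces the (K2, k_plus2) pair; unset both"
                )
            if self.composite3 is not None and (self.K3 is not None or self.k_plus3 != 0):
                raise InvalidParameterError(
                    "composite3 replaces the (K3, k_plus3) pair; unset both"
                )
        elif self.composite2 is not None or self.composite3 is not None:
            raise InvalidParameterError(
                "composite constants are only meaningful under variant 'parabolic'"
            )

    def evolve(self, **changes) -> "MechanismParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class AssayConditions:
    """Initial concentrations, duration and detection constants of one well.

    Absorbance follows Beer-Lambert: AU = epsilon * path_length * [NADH].
    The racemic substrate splits 1:1 into the fast and slow enantiomer
    (A0 = B0 = S_total / 2); the inhibitor is held at ``I_conc`` throughout
    (consumption by irreversible binding is <= 2 E_total and neglected).
    """

    E_total: float
    NAD0: float
    S_total: float
    I_conc: float = 0.0
    duration: float = 10800.0
    epsilon: float = 6220.0
    path_length: float = 0.9

    def __post_init__(self) -> None:
        for name in ("E_total", "NAD0", "S_total", "I_conc"):
            _require_nonneg(name, getattr(self, name))
        for name in ("duration", "epsilon", "path_length"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def A0(self) -> float:
        return self.S_total / 2.0

    @property
    def B0(self) -> float:
        return self.S_total / 2.0

    def evolve(self, **changes) -> "AssayConditions":
        return replace(self, **changes)


@dataclass(frozen=True)
class EnzymeSpeciesPartition:
    """Fractions of the *active* enzyme pool in each rapid-equilibrium state."""

    f_E: float
    f_ENAD: float
    f_ENADH: float
    f_ENAD_I: float
    f_ENADH_I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_E, self.f_ENAD, self.f_ENADH, self.f_ENAD_I, self.f_ENADH_I])


@dataclass(frozen=True)
class SlowState:
    """Slow dynamical variables: enantiomer concentrations and the
    irreversibly inactivated enzyme pool (all M).

    NADH, NAD and active enzyme are derived:
    NADH = A0 + B0 - A - B (1:1 stoichiometry), NAD = NAD0 - NADH,
    E_active = E_total - E_inact.
    """

    A: float
    B: float
    E_inact: float = 0.0

    def nadh(self, cond: AssayConditions) -> float:
        return cond.A0 + cond.B0 - self.A - self.B

    def nad(self, cond: AssayConditions) -> float:
        return cond.NAD0 - self.nadh(cond)

    def e_active(self, cond: AssayConditions) -> float:
        return cond.E_total - self.E_inact

    def validate(self, cond: AssayConditions, atol: float = 1e-12) -> None:
        if not (-atol <= self.A <= cond.A0 + atol and -atol <= self.B <= cond.B0 + atol):
            raise ValueError("enantiomer concentrations outside [0, initial]")
        if not (-atol <= self.E_inact <= cond.E_total + atol):
            raise ValueError("E_inact outside [0, E_total]")
        if self.nadh(cond) < -atol or self.nad(cond) < -atol:
            raise ValueError("derived coenzyme concentration negative")


@dataclass(frozen=True)
class SlowRates:
    """Time derivatives of the slow variables (M/s)."""

    dA: float
    dB: float
    dE_inact: float


def _ratio_terms(params: MechanismParams, nad, nadh, i_conc):
    """Dimensionless occupancy terms of the partition denominator.

    Returns (rN, rH, tI2, tI3) with rN = nad/K_NAD, rH = nadh/K_NADH and
    tI = i/K for each reversible inhibitor branch (0 when the branch is
    absent or replaced by a parabolic composite).
    """
    rN = nad / params.K_NAD
    rH = nadh / params.K_NADH
    tI2 = i_conc / params.K2 if params.K2 is not None else 0.0
    tI3 = i_conc / params.K3 if params.K3 is not None else 0.0
    return rN, rH, tI2, tI3


def partition_active_enzyme(
    params: MechanismParams, nad: float, nadh: float, i_conc: float
) -> EnzymeSpeciesPartition:
    """Partition the active enzyme among its rapid-equilibrium states.

    The denominator is ``D = 1 + (nad/K_NAD)(1 + i/K2) + (nadh/K_NADH)(1 +
    i/K3)``; a "not determined" K contributes nothing (K -> infinity), and
    under the parabolic variant the i/K term of the composite branch is
    likewise dropped.

    Parameters
    ----------
    nad, nadh, i_conc
        Free NAD+, NADH and inhibitor concentrations (M), all >= 0.

    Returns
    -------
    EnzymeSpeciesPartition
        Fractions summing to 1 by construction.
    """
    for name, v in (("nad", nad), ("nadh", nadh), ("i_conc", i_conc)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    rN, rH, tI2, tI3 = _ratio_terms(params, nad, nadh, i_conc)
    D = 1.0 + rN * (1.0 + tI2) + rH * (1.0 + tI3)
    return EnzymeSpeciesPartition(
        f_E=1.0 / D,
        f_ENAD=rN / D,
        f_ENADH=rH / D,
        f_ENAD_I=rN * tI2 / D,
        f_ENADH_I=rH * tI3 / D,
    )


def slow_rhs(state: SlowState, params: MechanismParams, cond: AssayConditions) -> SlowRates:
    """Right-hand side of the slow-variable ODE system.

    dA/dt = -k_spec1 [E.NAD] A and dB/dt = -k_spec2 [E.NAD] B with
    [E.NAD] = f_ENAD * E_active; the inactivation flux is
    k_plus * i * [E.NAD.I or E.NADH.I] per branch, or
    composite * i^2 * (x/K_coenzyme)/D * E_active under the parabolic
    variant (x = nad or nadh for the corresponding branch).
    """
    state.validate(cond)
    dA, dB, dE2, dE3 = _rhs_arrays(
        np.asarray([state.A]),
        np.asarray([state.B]),
        np.asarray([state.E_inact]),
        np.asarray([0.0]),
        params,
        A0=cond.A0,
        B0=cond.B0,
        NAD0=cond.NAD0,
        E_total=cond.E_total,
        i_conc=np.asarray([cond.I_conc]),
        sequestration=False,
    )
    return SlowRates(float(dA[0]), float(dB[0]), float(dE2[0] + dE3[0]))


def _rhs_arrays(A, B, E_inact2, E_inact3, params, *, A0, B0, NAD0, E_total,
                i_conc, frozen_coenzyme: bool = False,
                sequestration: bool = True, n_fixed_point: int = 4):
    """Vectorised RHS over parallel wells (used by the simulator).

    The inactivated pool is split by branch (``E_inact2`` formed from
    E.NAD.I carries NAD, ``E_inact3`` from E.NADH.I carries NADH) so that
    ``sequestration`` can correct the free-coenzyme mass balance for
    enzyme-bound coenzyme by fixed-point iteration.  That correction is
    only material when accumulated product is within ~an order of magnitude
    of E_total (strong inhibition); with ``sequestration=False`` the bulk
    balance NADH = A0 + B0 - A - B is used as-is.

    ``frozen_coenzyme`` pins NAD at NAD0 and disables the E.NADH terms —
    the regime in which the inhibitor-free model has a closed form.
    """
    A = np.clip(A, 0.0, None)
    B = np.clip(B, 0.0, None)
    E_inact = E_inact2 + E_inact3
    nadh_tot = np.clip(A0 + B0 - A - B, 0.0, None)
    E_active = np.clip(E_total - E_inact, 0.0, None)
    if frozen_coenzyme:
        nad = np.full_like(np.asarray(nadh_tot, dtype=float), NAD0)
        nadh = np.zeros_like(nad)
        rN, rH, tI2, tI3 = _ratio_terms(params, nad, nadh, i_conc)
        D = 1.0 + rN * (1.0 + tI2) + rH * (1.0 + tI3)
    else:
        nadh = nadh_tot
        nad = np.clip(NAD0 - nadh_tot, 0.0, None)
        iters = n_fixed_point if sequestration else 1
        for _ in range(iters):
            rN, rH, tI2, tI3 = _ratio_terms(params, nad, nadh, i_conc)
            D = 1.0 + rN * (1.0 + tI2) + rH * (1.0 + tI3)
            if not sequestration:
                break
            bound_nadh = E_active * rH * (1.0 + tI3) / D + E_inact3
            bound_nad = E_active * rN * (1.0 + tI2) / D + E_inact2
            nadh = np.clip(nadh_tot - bound_nadh, 0.0, None)
            nad = np.clip(NAD0 - nadh_tot - bound_nad, 0.0, None)
    enad = rN / D * E_active
    dA = -params.k_spec1 * enad * A
    dB = -params.k_spec2 * enad * B
    inact2 = params.k_plus2 * i_conc * (rN * tI2 / D)
    inact3 = params.k_plus3 * i_conc * (rH * tI3 / D)
    if params.composite2 is not None:
        inact2 = inact2 + params.composite2 * i_conc**2 * rN / D
    if params.composite3 is not None:
        inact3 = inact3 + params.composite3 * i_conc**2 * rH / D
    return dA, dB, inact2 * E_active, inact3 * E_active
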
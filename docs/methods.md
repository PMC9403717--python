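# Methods

## The model

`akrkin` models the spectrophotometric assay in which AKR1C1, AKR1C2 or
AKR1C3 oxidises racemic 1-acenaphthenol with NAD⁺, monitored as NADH
absorbance at 340 nm (ε = 6220 M⁻¹cm⁻¹, Beer–Lambert with a configurable
path length), and its inhibition by compounds that bind the holoenzymes in
two steps: a fast reversible association of one inhibitor molecule with
E·NAD or E·NADH (dissociation constants K₂, K₃), followed by a slow
irreversible association of a second molecule (second-order rate constants
k₊₂, k₊₃) that permanently inactivates the enzyme.

All binding steps (coenzyme and first inhibitor molecule) are treated as
instantaneous equilibria — the rapid-equilibrium approximation.  The active
enzyme partitions among five states with fractions proportional to

    E : 1
    E·NAD : nad/K_NAD          E·NAD·I : (nad/K_NAD)(i/K₂)
    E·NADH : nadh/K_NADH       E·NADH·I : (nadh/K_NADH)(i/K₃)

normalised by D = 1 + (nad/K_NAD)(1 + i/K₂) + (nadh/K_NADH)(1 + i/K₃).
A "not determined" K removes that branch (K → ∞); K = 0 is rejected as
distinct from "not determined".  Inhibitor binding to the apoenzyme is
excluded (its affinity is much lower than for the holoenzymes).

Only three kinds of slow variables are integrated per well: the two
substrate enantiomers A (fast) and B (slow) and the inactivated-enzyme
pools.  Turnover is bimolecular with no Michaelis saturation, because the
kinetics are parameterised solely by second-order specificity constants:

    dA/dt = −k_spec1 · f_E·NAD · E_active · A
    dB/dt = −k_spec2 · f_E·NAD · E_active · B
    dE_inact/dt = (k₊₂ · i · f_E·NAD·I + k₊₃ · i · f_E·NADH·I) · E_active

with NADH = A₀ + B₀ − A − B (1:1 stoichiometry), NAD = NAD₀ − NADH, and
E_active = E_total − E_inact.  By convention A is always the faster
enantiomer (k_spec1 ≥ k_spec2).  The inhibitor concentration is held
constant: consumption by irreversible binding is at most 2·E_total
(≤ 3 µM) against inhibitor ≥ 1 µM in the standard design.

**Parabolic variant.** When K and k₊ of a branch are not separately
identifiable (reversible binding saturates nowhere in the tested range),
only the composite k₊/K (M⁻²s⁻¹) enters: the i/K term is dropped from D and
the inactivation term becomes composite · i² · (x/K_coenzyme)/D · E_active
(x = nad or nadh).  The inactivation rate then grows with the square of the
inhibitor concentration — parabolic inhibition.  A `reversible_only`
variant fixes k₊₂ = k₊₃ = 0 for compounds with virtually no irreversible
component.

**Bound-coenzyme correction.** The naive bulk balance uses total product as
"NADH" in the partition.  At strong inhibition the 3-h product is only a
few µM, and the ≤ E_total of NADH sequestered as E·NADH(·I) or carried by
inactivated enzyme shifts the partition perceptibly (up to ~1% of final
NADH; a k_off-independent deviation from a full mass-action model).  The
simulator therefore solves the free NAD/NADH concentrations
self-consistently by fixed-point iteration (4 passes; the inactivated pool
is split by branch so each carries the right coenzyme).  `slow_rhs`
documents and exposes the plain bulk-balance right-hand side
(`sequestration=False` reproduces it exactly), which is also what the
hand-computed unit oracles pin.

## Oracles

Two independent checks validate the simulator:

1. **Closed form.**  With no inhibitor, NAD frozen at NAD₀ and E·NADH
   binding disabled, the system is linear and
   NADH(t) = A₀(1 − e^(−λ₁t)) + B₀(1 − e^(−λ₂t)) with
   λᵢ = k_spec,i · E_total · f, f = (NAD₀/K_NAD)/(1 + NAD₀/K_NAD).
   The simulator matches this to < 10⁻⁶ relative.
2. **Full mass action.**  Every equilibrium is expanded with explicit rates
   (k_off = 10³ s⁻¹, k_on = k_off/K) and integrated with BDF.  Agreement of
   final NADH improves monotonically with k_off, confirming the
   rapid-equilibrium limit.  The catalytic step of the oracle defaults to
   releasing product NADH directly to the bulk — the same convention as the
   reduced model — so the comparison isolates the one approximation under
   test.  The chemically faithful routing through E·NADH
   (`product_release="via_enadh"`) is also available; at finite off-rates
   it adds a kinetic-partitioning effect (enzyme emerging from turnover is
   captured by a nM-affinity inhibitor before releasing NADH) that
   accelerates inactivation and that no rapid-equilibrium model can
   represent.  This is a genuine limitation of the reduction for
   strong-binding inhibitors at high concentrations, not a defect of either
   integrator.

## Estimation

Fitting follows a two-stage protocol mirroring how the constants are
organised: the coenzyme dissociation constants (K_NAD = 0.16 mM,
K_NADH = 0.61 mM) and enantiomer specificity constants are determined from
inhibitor-free controls and then held fixed while K₂/k₊₂/K₃/k₊₃ (or the
composites) are estimated from the full concentration series.  The
objective is the unweighted sum of squared absorbance residuals over every
curve — replicates and experimental data sets jointly, with one shared
parameter vector (a 1/σ² weight hook exists but homoscedastic read noise
makes it moot).  Parameters are optimised as natural logarithms
(positivity, scale-free steps) with `scipy.optimize.least_squares`
(trust-region reflective).  Because K and k₊ of a branch are strongly
correlated, fits are multistarted: a data-driven heuristic seed (K from the
geometric mean of the tested concentrations, k₊ from 1/(i_min·duration))
plus Latin-hypercube draws within ±2 decades, 8 starts by default.
Standard errors come from the Jacobian at the optimum
(σ²(JᵀJ)⁻¹ on the log scale, delta-method to linear scale).

**Variant selection** fits all three candidates and reports RSS, AICc and
the condition number of the scaled JᵀJ.  Rules: *parabolic* when the full
fit leaves both K and k₊ of a branch with relative SE > 100% while the
relative SE of their ratio is < 25% (covariance-based, delta method) and
parabolic is at least as parsimonious as reversible-only; *reversible_only*
when no k₊ estimate is significantly positive (estimate − 1.96·SE ≤ 0 —
the criterion behind "virtually no irreversible inhibition", which had to
be chosen here) or when it has the best AICc; otherwise *full*.

## Synthetic data

The generator emulates the published assay design: 2.3 mM NAD⁺; substrate
90/180/250 µM and enzyme 0.11/0.16/1.5 µM for AKR1C1/2/3; seven inhibitor
concentrations log-spaced over 1–200 µM plus an inhibitor-free control;
duplicate or triplicate wells (default 3); 3 h duration.  Values not
reported anywhere had to be fixed once: reads every 60 s (181 samples), a
0.9 cm effective path for 300 µL in a 96-well plate, and additive
homoscedastic Gaussian absorbance noise of sd 0.002 AU (typical
plate-reader read noise; stress range 0.001–0.005), optional linear
baseline drift, seed mandatory.  Recoveries are insensitive to the path
length and read interval as long as generator and fitter share them.

What a green recovery test establishes: the estimator returns the
generating constants from data whose noise structure it assumes.  It does
not establish robustness to heteroscedastic noise, well-position or
evaporation artifacts, temperature drift, inhibitor depletion or substrate
impurities — none of which the generator emulates.

## Numerical choices

- Slow system: LSODA, rtol 10⁻⁸ / atol 10⁻¹² M, states interleaved
  (A, B, E_inact²-branch, E_inact³-branch) per well so many wells integrate
  in one call with a banded (lband = uband = 3) Jacobian.
- Mass-action oracle: BDF at rtol 10⁻⁸ / atol 10⁻¹³ (LSODA shows
  convergence failures at k_on·i ~ 10¹⁰ s⁻¹ stiffness).
- Fit invariance: curves are sorted into a canonical order before residual
  stacking, so estimates are bit-identical under permutation of the input.
- Degenerate inputs: flat control curves (span < 10⁻⁴ AU) raise a
  non-identifiability error rather than returning garbage; fits require ≥ 3
  distinct concentrations including a 0-µM control.
- 4PL dose-response: fit on log-dose with hill > 0 and top ≥ bottom
  enforced by parameterisation (bottom + e^s); 95% CI asymptotic on
  ln IC50; a response span < 0.1 raises a no-transition error.
- Fold ratios are printed at 2 significant figures, constants at 3, per the
  field's reporting convention; full precision is kept in JSON.

## Known limitations

- Inhibitor depletion is not tracked (held-constant approximation); the
  error is bounded by 2·E_total/i and is worst for AKR1C3 (1.5 µM enzyme)
  at 1 µM inhibitor.
- The rapid-equilibrium reduction under-predicts inactivation whenever
  binding relaxation is not truly fast relative to the catalytic flux (see
  the `via_enadh` oracle discussion above).
- Replicates are fit individually, not averaged; how the original analyses
  weighted replicates is unknown.
- Temperature is metadata only; no Arrhenius correction of constants.
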
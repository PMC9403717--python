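# akrkin

Progress-curve kinetics of aldo-keto reductase (AKR1C1–3) inhibition by
two-step-binding metalloinhibitors — simulation, synthetic plate-reader
data, global fitting, and dose-response support.

## The problem

AKR1C enzymes are drug targets in hormone-dependent and chemoresistant
cancers.  Their inhibition by organometallic (e.g. ruthenium) complexes is
kinetically unusual: a first inhibitor molecule binds the holoenzymes
E·NAD and E·NADH rapidly and reversibly (dissociation constants K₂ and
K₃), and a second molecule then associates slowly and irreversibly (rate
constants k₊₂ and k₊₃), permanently inactivating the enzyme.  Neither a
single IC50 nor a classical Ki captures this; the constants must be
estimated by fitting full NADH-absorbance progress curves (340 nm,
ε = 6220 M⁻¹cm⁻¹, 3 h) across an inhibitor concentration series.

`akrkin` is for enzymologists and modellers who want to simulate such
assays, generate realistic synthetic plates with known ground truth, and
estimate the scheme's constants by global nonlinear least squares.

## The model

Active enzyme is partitioned instantaneously among E, E·NAD, E·NADH,
E·NAD·I and E·NADH·I with denominator

    D = 1 + (nad/K_NAD)(1 + i/K₂) + (nadh/K_NADH)(1 + i/K₃),

and only slow variables are integrated: the racemate's fast and slow
enantiomers (A₀ = B₀ = S_total/2) and the inactivated enzyme pool,

    dA/dt      = −k_spec1 [E·NAD] A,        [E·NAD] = f_E·NAD · E_active
    dB/dt      = −k_spec2 [E·NAD] B
    dE_inact/dt = (k₊₂ i f_E·NAD·I + k₊₃ i f_E·NADH·I) E_active,

with NADH = A₀ + B₀ − A − B and absorbance = ε·l·NADH.  Model variants:
`full`, `reversible_only` (k₊ = 0), and `parabolic` (only the composite
k₊/K identifiable; inactivation ∝ i²).  See `docs/methods.md` for the
assumptions, the bound-coenzyme correction and the validation oracles.

## Worked example

```python
import akrkin as ak

shared = ak.constants.SHARED_CONSTANTS["AKR1C1"]      # K_NAD, K_NADH, k_spec1/2
truth  = ak.MechanismParams(**shared, K3=21.4e-9, k_plus3=9.4)
design = ak.default_assay_design("AKR1C1")            # 90 uM substrate, 0.11 uM enzyme,
                                                      # 2.3 mM NAD+, 7 concs + control
plate  = ak.generate_curveset(truth, design, ak.NoiseModel(sd=0.002, seed=3))

stage1 = ak.fit_substrate_constants(plate.controls())
fit    = ak.fit_inhibition(plate, {**stage1.fixed, **stage1.params},
                           {"K3": None, "k_plus3": None}, variant="full")
print(fit.summary())
```

prints

```
variant=full  rss=0.0173538  n=4344  converged=True
  K3 = 2.138e-08 +/- 3.1e-11
  k_plus3 = 9.413 +/- 0.024
```

i.e. from one noisy synthetic plate (0.002 AU read noise, 24 wells, 4344
absorbance readings) the nanomolar dissociation constant of the E·NADH·I
complex is recovered as 21.4 ± 0.03 nM against a generating truth of
21.4 nM, and the irreversible rate constant as 9.41 ± 0.02 M⁻¹s⁻¹
against 9.4.

The numbered drivers under `analysis/` run the full studies (simulation
atlas, substrate-constant recovery, inhibition-constant Monte Carlo,
parabolic-variant identifiability, oracle validation, selectivity/IC50
tables) and write their tables to `results/`.

A command-line interface mirrors the pipeline:

```
akrkin generate --enzyme AKR1C1 --params params.yaml --seed 42 -o curves.csv
akrkin fit curves.csv --enzyme AKR1C1 --variant auto --seed 7 -o fit.json
akrkin report -o selectivity.tsv
akrkin ic50 viability.csv -o ic50.json
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates noiseless inhibitor-free AKR1C1 control curves under the
standard assay design, re-estimates the enantiomer specificity constants
with the coenzyme constants held fixed, and writes the recovered
fast-enantiomer constant (M⁻¹s⁻¹) as JSON.
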
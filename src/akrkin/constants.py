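"""Published constants for the AKR1C1-3 / ruthenium-complex system.

All concentrations are molar (SI) unless a unit suffix in the name says
otherwise.  These values are inputs to recovery studies and selectivity
reports; nothing in the package derives them at run time.
"""

from __future__ import annotations

# Molar absorptivity of NADH at 340 nm (M^-1 cm^-1).
EPSILON_NADH_340 = 6220.0

# Coenzyme dissociation constants shared by all three isoforms (M) and the
# per-isoform second-order specificity constants of the two substrate
# enantiomers (M^-1 s^-1), determined from inhibitor-free reactions.
SHARED_CONSTANTS = {
    "AKR1C1": {"K_NAD": 0.16e-3, "K_NADH": 0.61e-3, "k_spec1": 16920.0, "k_spec2": 1580.0},
    "AKR1C2": {"K_NAD": 0.16e-3, "K_NADH": 0.61e-3, "k_spec1": 3000.0, "k_spec2": 140.0},
    "AKR1C3": {"K_NAD": 0.16e-3, "K_NADH": 0.61e-3, "k_spec1": 230.0, "k_spec2": 38.0},
}

# Assay design per isoform: total racemic 1-acenaphthenol and total enzyme.
ASSAY_DEFAULTS = {
    "AKR1C1": {"S_total": 90e-6, "E_total": 0.11e-6},
    "AKR1C2": {"S_total": 180e-6, "E_total": 0.16e-6},
    "AKR1C3": {"S_total": 250e-6, "E_total": 1.5e-6},
}
NAD0_DEFAULT = 2.3e-3  # initial NAD+ (M)

# Published inhibition constants per compound and isoform.  K2 (M) and
# k_plus2 (M^-1 s^-1) describe reversible binding to E.NAD and irreversible
# binding of a second inhibitor to E.NAD.I; K3 (M) and k_plus3 the same for
# the E.NADH branch.  None = not determined for that compound/isoform.
# Compounds 9 and 10 (in part) showed virtually no irreversible inhibition.
INHIBITION_CONSTANTS = {
    1: {
        "AKR1C1": {"K2": None, "k_plus2": None, "K3": 21.4e-9, "k_plus3": 9.4},
        "AKR1C2": {"K2": 305e-6, "k_plus2": None, "K3": 52.7e-9, "k_plus3": 7.7},
        "AKR1C3": {"K2": 105e-6, "k_plus2": None, "K3": 163e-9, "k_plus3": 0.9},
    },
    2: {
        "AKR1C1": {"K2": 2.8e-6, "k_plus2": 25.9, "K3": None, "k_plus3": None},
        "AKR1C2": {"K2": 80e-6, "k_plus2": 12.6, "K3": None, "k_plus3": None},
        "AKR1C3": {"K2": 116e-6, "k_plus2": 5.3, "K3": None, "k_plus3": None},
    },
    3: {
        "AKR1C1": {"K2": 107e-6, "k_plus2": 31.5, "K3": 42.9e-9, "k_plus3": 4.3},
        "AKR1C2": {"K2": 157e-6, "k_plus2": 7.4, "K3": 1125e-9, "k_plus3": 55.4},
        "AKR1C3": {"K2": 179e-6, "k_plus2": 10.2, "K3": 306e-9, "k_plus3": 1.2},
    },
    4: {
        "AKR1C1": {"K2": 86.9e-6, "k_plus2": 1.4, "K3": None, "k_plus3": None},
        "AKR1C2": {"K2": 340e-6, "k_plus2": 1.9, "K3": None, "k_plus3": None},
        "AKR1C3": {"K2": 441e-6, "k_plus2": 1.8, "K3": None, "k_plus3": None},
    },
    5: {
        "AKR1C1": {"K2": None, "k_plus2": None, "K3": 23.5e-9, "k_plus3": 6.0},
        "AKR1C2": {"K2": None, "k_plus2": None, "K3": 66.2e-9, "k_plus3": 7.3},
        "AKR1C3": {"K2": None, "k_plus2": None, "K3": 150e-9, "k_plus3": 0.5},
    },
    6: {
        "AKR1C1": {"K2": 3.1e-6, "k_plus2": 48.8, "K3": None, "k_plus3": None},
        "AKR1C2": {"K2": 8.3e-6, "k_plus2": 172.0, "K3": None, "k_plus3": None},
        "AKR1C3": {"K2": 92.7e-6, "k_plus2": 90.0, "K3": None, "k_plus3": None},
    },
    7: {
        "AKR1C1": {"K2": None, "k_plus2": None, "K3": 345e-9, "k_plus3": 17.1},
        "AKR1C2": {"K2": None, "k_plus2": None, "K3": 65.4e-9, "k_plus3": 11.1},
        # parabolic inhibition: only the composite k_plus3/K3 is identifiable
        "AKR1C3": {"composite3": 1.63e6},
    },
    8: {
        "AKR1C1": {"K2": 0.35e-6, "k_plus2": 2943.0, "K3": None, "k_plus3": None},
        "AKR1C2": {"K2": 1.6e-6, "k_plus2": 929.0, "K3": None, "k_plus3": None},
        "AKR1C3": {"composite3": 1.97e6},
    },
    9: {
        "AKR1C1": {"K2": 227e-6, "k_plus2": 0.0, "K3": None, "k_plus3": None},
        "AKR1C2": {"K2": 191e-6, "k_plus2": 0.0, "K3": None, "k_plus3": None},
        "AKR1C3": {"K2": 439e-6, "k_plus2": 0.0, "K3": None, "k_plus3": None},
    },
    10: {
        "AKR1C1": {"K2": 49.7e-6, "k_plus2": 13.5, "K3": None, "k_plus3": None},
        "AKR1C2": {"K2": 42.5e-6, "k_plus2": 5.1, "K3": None, "k_plus3": None},
        "AKR1C3": {"K2": 561e-6, "k_plus2": 0.0, "K3": None, "k_plus3": None},
    },
}

# Published cell-viability IC50 values (uM) for ovarian cell lines; None =
# not measured or not accurately calculable (> bounds reported as None here).
VIABILITY_IC50_UM = {
    "1": {"HIO80": 41.88, "COV362": 96.59, "OVCAR-4": None},
    "2": {"HIO80": 92.05, "COV362": 140.7, "OVCAR-4": None},
    "3": {"HIO80": 34.72, "COV362": 90.22, "OVCAR-4": None},
    "5": {"HIO80": 60.50, "COV362": 136.20, "OVCAR-4": None},
    "6": {"HIO80": 187.3, "COV362": 151.50, "OVCAR-4": None},
    "7": {"HIO80": 14.32, "COV362": 17.67, "OVCAR-4": 28.05},
    "8": {"HIO80": 32.54, "COV362": 38.04, "OVCAR-4": 97.50},
    "9": {"HIO80": 12.76, "COV362": 21.53, "OVCAR-4": 14.36},
    "cisplatin": {"HIO80": 6.96, "COV362": 13.55, "OVCAR-4": 4.16},
    "carboplatin": {"HIO80": 131.30, "COV362": 271.60, "OVCAR-4": 73.02},
}

ENZYMES = ("AKR1C1", "AKR1C2", "AKR1C3")
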
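import numpy as np
import pytest

import akrkin as ak


@pytest.fixture(scope="session")
def shared_c1():
    """Shared coenzyme/substrate constants of AKR1C1 (SI units)."""
    return dict(ak.constants.SHARED_CONSTANTS["AKR1C1"])


@pytest.fixture(scope="session")
def params_c1(shared_c1):
    """Inhibitor-free AKR1C1 parameter set."""
    return ak.MechanismParams(**shared_c1)


@pytest.fixture(scope="session")
def design_c1():
    return ak.default_assay_design("AKR1C1")


@pytest.fixture(scope="session")
def coarse_design_c1():
    """Reduced sampling/replication for expensive repeated fits."""
    return ak.default_assay_design("AKR1C1").evolve(interval=300.0, replicates=2)


@pytest.fixture(scope="session")
def cond_c1(design_c1):
    return design_c1.conditions(0.0)


@pytest.fixture(scope="session")
def fast_opts():
    return ak.FitOptions(n_starts=2, xtol=1e-10, ftol=1e-10)
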
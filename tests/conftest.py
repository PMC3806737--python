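import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import memsono as ms

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

#: Reference configuration: the 100-pF bilayer simulation (water at
#: room temperature, decane-containing phospholipid bilayer, 10-ms
#: radiation-force step).
REF_CONFIG = {
    "d": 120e-6,
    "gamma": 0.8e-3,
    "P0": -70.0,
    "P_US": 0.15,
    "t_on": 5e-3,
    "t_off": 15e-3,
}


@pytest.fixture(scope="session")
def ref_result():
    """Full pipeline run for the reference parameter set (201 nodes)."""
    return ms.run_pipeline(dict(REF_CONFIG))


@pytest.fixture(scope="session")
def ref_objects():
    bp = ms.BilayerParameters(d=REF_CONFIG["d"], gamma=REF_CONFIG["gamma"])
    med = ms.MediumProperties()
    prog = ms.PressureProgram(P0=REF_CONFIG["P0"], P_US=REF_CONFIG["P_US"],
                              t_on=REF_CONFIG["t_on"], t_off=REF_CONFIG["t_off"])
    return bp, med, prog


@pytest.fixture(scope="session")
def fast_settings():
    """Coarser grid for tests that need several PDE solves."""
    return ms.SolverSettings(n_nodes=101, rtol=1e-8, dt_out=1e-5)
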
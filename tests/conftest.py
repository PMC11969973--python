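import numpy as np
import pytest

from mlrgait import config


@pytest.fixture(scope="session")
def cfg():
    c = config.default_config()
    config.validate_config(c)
    return c


@pytest.fixture(scope="session")
def passive_cfg(cfg):
    """Configuration with every dissipative/active element disabled.

    Muscles produce no force, joints have no viscosity, and the
    joint-limit stiffnesses are moved out of reach, so short airborne
    trajectories are conservative (used by the energy/momentum oracles).
    """
    import copy

    c = copy.deepcopy(cfg)
    for m in c["muscles"].values():
        m["c_PD"] = 0.0
        m["k_PE"] = 0.0
        m["F_CE"] = 1e-12  # validator requires > 0; force is alpha-gated anyway
    jv = c["body"]["joints"]["viscosity"]
    jv["hip"] = jv["knee"] = jv["ankle"] = 0.0
    c["body"]["joints"]["knee"]["range"] = [-50.0, 50.0]
    c["body"]["joints"]["ankle"]["range"] = [-50.0, 50.0]
    return c


@pytest.fixture(scope="session")
def zero_controller():
    """All-zero free parameters except a token CnF->CPG weight."""
    vec = np.zeros(49)
    return vec
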
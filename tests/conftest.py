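import numpy as np
import pytest

from npqtau import default_truth, parse_light_sequence
from npqtau.parameters import apply_genotype


@pytest.fixture(scope="session")
def truth():
    """Ground-truth kinetic parameters, quenching constants, registry."""
    kin, q, reg = default_truth()
    return kin, q, reg


@pytest.fixture(scope="session")
def wt_setup(truth):
    kin, q, reg = truth
    g = reg["WT"]
    return g, apply_genotype(kin, g), q


@pytest.fixture(scope="session")
def seq_5hl():
    return parse_light_sequence("5HL-10D-5HL")


@pytest.fixture(scope="session")
def seq_20hl():
    return parse_light_sequence("20HL")


def theta_truth(kin, q, names):
    """Map fit-parameter names to their generating values."""
    out = {}
    for n in names:
        if n.startswith("V_0_"):
            out[n] = 28.0
        elif hasattr(kin, n):
            out[n] = getattr(kin, n)
        else:
            out[n] = getattr(q, n)
    return out
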
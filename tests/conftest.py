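import numpy as np
import pytest

from vocalcpg.cpg import CPGParams, OscillatorParams, constant_drive, integrate_cpg


@pytest.fixture(scope="session")
def params():
    """Published default parameter set."""
    return CPGParams()


@pytest.fixture(scope="session")
def uncoupled_params():
    """Defaults with both couplings removed (independent oscillators)."""
    p = CPGParams()
    return CPGParams(
        resp=OscillatorParams(p.resp.gamma, p.resp.a_min, p.resp.a_max, 0.0),
        lar=OscillatorParams(p.lar.gamma, p.lar.a_min, p.lar.a_max, 0.0),
        p0=p.p0, k0=p.k0, x20=p.x20,
    )


@pytest.fixture(scope="session")
def uncoupled_mid_trace(uncoupled_params):
    """Uncoupled run at mid drive: both oscillators on their limit cycles."""
    return integrate_cpg(uncoupled_params, constant_drive(0.5, 30.0))


@pytest.fixture(scope="session")
def coupled_mid_trace(params):
    """Coupled run at mid drive under the default sweep protocol."""
    return integrate_cpg(params, constant_drive(0.5, 30.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
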
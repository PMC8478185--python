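import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

import vclamp as vc
from vclamp.biophys import GatingSpec, IonicCurrentSpec, NeuronModel
from vclamp.protocols import (
    CurrentStepProtocol,
    SynapticBombardmentProtocol,
    make_bombardment_drive,
)


@pytest.fixture(scope="session")
def gate():
    return GatingSpec(V_half=-40.0, V_slope=10.0, tau_max=8.0, tau_min=1.0,
                      V_tau_half=-45.0, V_tau_slope=20.0, p=2)


@pytest.fixture(scope="session")
def passive_cell():
    """Single effective compartment: couplings zero, only somatic leak."""
    return NeuronModel(
        C=(20.0, 1.0, 1.0),
        g_leak=(2.0, 0.0, 0.0),
        E_leak=(-65.0, -65.0, -65.0),
        g_sx=0.0,
        g_sd=0.0,
        currents=(),
        calcium=None,
        phenotype="passive",
    )


@pytest.fixture(scope="session")
def short_protocol():
    """A cheap 8-sweep step protocol for plumbing tests."""
    return CurrentStepProtocol(start=-20.0, increment=5.0, stop=15.0,
                               duration=200.0, cycle=400.0, onset=100.0)


@pytest.fixture(scope="session")
def drive():
    """The default bombardment drive, shared across tests."""
    return make_bombardment_drive(SynapticBombardmentProtocol(), seed=1)


@pytest.fixture(scope="session")
def canonical():
    return {ph: vc.canonical_model(ph) for ph in ("regular", "delayed", "stuttering")}


@pytest.fixture(scope="session")
def regular_static(canonical):
    """Full static protocol on the canonical regular model (reused widely)."""
    from vclamp.protocols import run_static_protocol

    return run_static_protocol(canonical["regular"])
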
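import numpy as np
import pytest

from protoforge.kinetics import KineticParameters, RateLaw
from protoforge.netio import NetworkModel, Reaction, Species
from protoforge.reactorsim import (MembraneSpec, ProtosensorModel, Reservoir,
                                   Trace)


@pytest.fixture
def tiny_network():
    """E catalyzes S -> P."""
    return NetworkModel(
        species=[Species(id="S"), Species(id="P", role="reporter"),
                 Species(id="E", role="enzyme")],
        reactions=[Reaction(id="R1", substrates=[("S", 1)],
                            products=[("P", 1)], enzyme="E")],
        metadata={"source": "tiny"})


@pytest.fixture
def uptake_model_factory():
    """Permeable substrate S taken up and converted to retained P (mm_uni).

    Concentrations are nM-scale so exact SSA trajectories stay cheap at the
    10-um geometry.
    """
    net = NetworkModel(
        species=[Species(id="S"), Species(id="P", role="reporter"),
                 Species(id="E", role="enzyme")],
        reactions=[Reaction(id="R1", substrates=[("S", 1)],
                            products=[("P", 1)], enzyme="E")])
    kin = KineticParameters(laws={
        "R1": RateLaw(mechanism="mm_uni", kcat=0.5, Km_map={"S": 1e-7})})

    def make(diameter_um=10.0, permeability=0.2, s_out=2e-8, e_conc=2e-9,
             pore_scale=1.0):
        return ProtosensorModel(
            network=net, kinetics=kin,
            membrane=MembraneSpec(permeability={"S": permeability},
                                  pore_scale=pore_scale),
            diameter_um=diameter_um,
            interior_initial={"E": e_conc}, exterior={"S": s_out},
            reservoir=Reservoir())

    return make


@pytest.fixture
def step_trace():
    """Simple 5-point trace used by the temporal-logic tests."""
    times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    return Trace(times=times,
                 concentrations={"X": np.array([0.0, 1.0, 3.7, 2.0, 1.5]),
                                 "Y": np.array([5.0, 4.0, 3.0, 2.0, 1.0])})
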
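import numpy as np
import pytest

from evoplast.network import Connection, Neuron, PlasticityParams, PlasticNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, n_hidden=6, n_inputs=3, n_outputs=2, p_mod=0.3, p_edge=0.4):
    """Random plastic network for fuzz/oracle tests."""
    neurons = [Neuron(f"i{k}", "input") for k in range(n_inputs)]
    for k in range(n_hidden):
        kind = "modulatory" if rng.random() < p_mod else "standard"
        neurons.append(Neuron(f"h{k}", "hidden", kind, float(rng.uniform(-1, 1))))
    neurons += [Neuron(f"o{k}", "output", bias=float(rng.uniform(-1, 1))) for k in range(n_outputs)]
    ids = [m.id for m in neurons]
    non_inputs = [m.id for m in neurons if m.role != "input"]
    conns = []
    seen = set()
    for src in ids:
        for tgt in non_inputs:
            if rng.random() < p_edge and (src, tgt) not in seen:
                seen.add((src, tgt))
                conns.append(
                    Connection(src, tgt, int(rng.choice([-1, 1])), float(rng.uniform(0, 2)))
                )
    return PlasticNetwork(neurons, conns)


@pytest.fixture
def random_network_factory():
    return random_network
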
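"""Canonical networks for validation.

``make_fixture`` builds deterministic reference objects: graphs whose
automorphism counts are known in closed form (fully connected, layered
perceptrons, the lamprey central-pattern-generator topology with its two
axial symmetries) and ``hand_learner``, a hand-wired plastic network that
solves the operant-conditioning task, used to validate the whole pipeline
end to end.
"""

from __future__ import annotations

from typing import Sequence

from .network import Connection, Neuron, PlasticityParams, PlasticNetwork


def fully_connected(n: int = 4, weight: float = 1.0) -> PlasticNetwork:
    """Complete digraph (no self-loops) with uniform weights: every vertex
    is interchangeable, so the automorphism count is n!."""
    neurons = [Neuron(i, "hidden") for i in range(n)]
    conns = [
        Connection(i, j, 1, weight) for i in range(n) for j in range(n) if i != j
    ]
    return PlasticNetwork(neurons, conns)


def mlp(layer_sizes: Sequence[int], weight: float = 1.0) -> PlasticNetwork:
    """Layered feed-forward net, consecutive layers fully connected with
    uniform weights: within-layer swaps give prod(k!) automorphisms."""
    neurons = []
    ids = []
    for li, size in enumerate(layer_sizes):
        role = "input" if li == 0 else ("output" if li == len(layer_sizes) - 1 else "hidden")
        layer = []
        for k in range(size):
            nid = f"l{li}.{k}"
            neurons.append(Neuron(nid, role))
            layer.append(nid)
        ids.append(layer)
    conns = [
        Connection(a, b, 1, weight)
        for la, lb in zip(ids, ids[1:])
        for a in la
        for b in lb
    ]
    return PlasticNetwork(neurons, conns)


def lamprey_cpg() -> PlasticNetwork:
    """Segmental central-pattern-generator topology of the lamprey spinal
    cord: four segments of left/right oscillator units with crossed
    (contralateral) inhibition and bidirectional rostro-caudal excitatory
    coupling.  The chain has a top-down and a left-right axial symmetry,
    hence 2 x 2 = 4 automorphisms."""
    rows = 4
    neurons = [Neuron(f"{side}{r}", "hidden") for r in range(rows) for side in "LR"]
    conns = []
    for r in range(rows):
        conns.append(Connection(f"L{r}", f"R{r}", -1, 1.0))
        conns.append(Connection(f"R{r}", f"L{r}", -1, 1.0))
    for r in range(rows - 1):
        for side in "LR":
            conns.append(Connection(f"{side}{r}", f"{side}{r+1}", 1, 1.0))
            conns.append(Connection(f"{side}{r+1}", f"{side}{r}", 1, 1.0))
    return PlasticNetwork(neurons, conns)


def random_rigid() -> PlasticNetwork:
    """Small asymmetric digraph with only the identity automorphism."""
    neurons = [Neuron(i, "hidden") for i in range(5)]
    conns = [Connection(a, b, 1, 1.0) for a, b in [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2)]]
    return PlasticNetwork(neurons, conns)


def hand_learner(params: PlasticityParams | None = None) -> PlasticNetwork:
    """Hand-wired network that learns the 4x4 operant-conditioning task.

    Architecture: a plastic stimulus fan s_i -> h_j (the association
    memory), relay units h_j driving the outputs through fixed strong
    connections, and per-action modulatory gates.  M_j fires only when
    action j's feedback line AND the positive reward are both on and sends
    positive modulation to h_j; N_j is its mirror for the negative reward
    and sends negative modulation.  Rewarded choices therefore strengthen
    exactly the active stimulus->relay weight of the chosen action, and
    punished choices weaken it.

    One imperfection is inherent to the synchronous model: on the first
    step after a new stimulus is clamped, the gates still carry the
    previous association's reward state, so a small fraction of each
    update leaks onto the next stimulus's weights.  The learner still
    reaches a set-level GLA score two orders of magnitude above chance.
    """
    p = params if params is not None else PlasticityParams()
    w = p.w_max  # strong fixed weight
    neurons = []
    conns = []
    for i in range(4):
        neurons.append(Neuron(f"s{i}", "input", label=f"stimulus-{i}"))
    neurons.append(Neuron("rpos", "input", label="reward-pos"))
    neurons.append(Neuron("rneg", "input", label="reward-neg"))
    for i in range(4):
        neurons.append(Neuron(f"f{i}", "input", label=f"feedback-{i}"))
    for j in range(4):
        neurons.append(Neuron(f"h{j}", "hidden", bias=-0.25))
        neurons.append(Neuron(f"M{j}", "hidden", "modulatory", bias=-4.0))
        neurons.append(Neuron(f"N{j}", "hidden", "modulatory", bias=-4.0))
    for j in range(4):
        neurons.append(Neuron(f"a{j}", "output", bias=-1.0, label=f"action-{j}"))
    for i in range(4):
        for j in range(4):
            conns.append(Connection(f"s{i}", f"h{j}", 1, w / 2))  # plastic fan
    for j in range(4):
        conns.append(Connection(f"h{j}", f"a{j}", 1, w))
        conns.append(Connection(f"f{j}", f"M{j}", 1, w))
        conns.append(Connection(f"rpos", f"M{j}", 1, w))
        conns.append(Connection(f"f{j}", f"N{j}", 1, w))
        conns.append(Connection(f"rneg", f"N{j}", 1, w))
        conns.append(Connection(f"M{j}", f"h{j}", 1, w))
        conns.append(Connection(f"N{j}", f"h{j}", -1, w))
    return PlasticNetwork(neurons, conns, p)


def zero_network() -> PlasticNetwork:
    """Task-shaped network with all-zero weights and biases: its outputs
    are always equal, so action selection is uniform (chance level)."""
    neurons = [Neuron(f"s{i}", "input", label=f"stimulus-{i}") for i in range(4)]
    neurons += [
        Neuron("rpos", "input", label="reward-pos"),
        Neuron("rneg", "input", label="reward-neg"),
    ]
    neurons += [Neuron(f"f{i}", "input", label=f"feedback-{i}") for i in range(4)]
    neurons += [Neuron(f"a{i}", "output", label=f"action-{i}") for i in range(4)]
    conns = [
        Connection(m.id, f"a{j}", 1, 0.0)
        for m in neurons
        if m.role == "input"
        for j in range(4)
    ]
    return PlasticNetwork(neurons, conns)


_FIXTURES = {
    "fully_connected": fully_connected,
    "mlp": mlp,
    "lamprey_cpg": lamprey_cpg,
    "random_rigid": random_rigid,
    "hand_learner": hand_learner,
    "zero_network": zero_network,
}


def make_fixture(name: str, *args, **kwargs) -> PlasticNetwork:
    """Build a canonical fixture by name; see module docstring."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return _FIXTURES[name](*args, **kwargs)
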
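"""Minimal-HyperNEAT encoding (HNN).

Neurons sit at fixed 3D coordinates in a substrate; two Compositional
Pattern Producing Networks (CPPNs) are queried over those coordinates to
paint the network onto it.  A connection-centred CPPN, queried with the
coordinates of an ordered neuron pair, returns a link-expression output
(LEO, thresholded to decide whether the connection exists) and the signed
synaptic weight; a node-centred CPPN, queried with one neuron's
coordinates, returns the bias and a kind output (modulatory if below the
0.4 cutoff, hidden neurons only).  Both CPPNs are plain feed-forward
function graphs evolved with the direct encoding (no NEAT speciation).

Because the CPPNs are smooth functions of coordinates, symmetries of the
substrate translate into symmetries of the developed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..network import Connection, Neuron, PlasticityParams, PlasticNetwork
from .base import DevelopmentError, GraphGenotype, MutationRates
from .direct import DirectEncoding, make_cppn_encoding


class CppnCycleError(DevelopmentError):
    """CPPN graph contains a directed cycle; it cannot be evaluated."""


# Activation-function alphabet, selected by the per-node "func" gene.
CPPN_FUNCS = ("sine", "sigmoid", "gaussian", "linear")


def _apply_func(idx: int, x: float) -> float:
    if idx == 0:
        return float(np.sin(x))
    if idx == 1:
        return float(1.0 / (1.0 + np.exp(-x)))
    if idx == 2:
        return float(np.exp(-x * x))
    return float(x)


def cppn_eval(cppn: GraphGenotype, inputs: np.ndarray) -> np.ndarray:
    """Topological-order evaluation of a CPPN genotype.

    Input nodes pass their value through; every other node computes
    f(sum of signed weighted inputs + bias) with f its function gene.
    Raises :class:`CppnCycleError` on recurrent wiring.
    """
    in_ids = cppn.node_ids("input")
    out_ids = cppn.node_ids("output")
    x = np.asarray(inputs, dtype=float)
    if x.shape != (len(in_ids),):
        raise ValueError(f"expected {len(in_ids)} CPPN inputs, got {x.shape}")

    preds: Dict[int, list] = {nid: [] for nid in cppn.nodes}
    indeg = {nid: 0 for nid in cppn.nodes}
    for e in cppn.edges.values():
        preds[e.target].append(e)
        indeg[e.target] += 1

    value: Dict[int, float] = {}
    ready = [nid for nid in cppn.node_ids() if indeg[nid] == 0]
    order = []
    while ready:
        nid = ready.pop()
        order.append(nid)
        for e in cppn.edges.values():
            if e.source == nid:
                indeg[e.target] -= 1
                if indeg[e.target] == 0:
                    ready.append(e.target)
    if len(order) != len(cppn.nodes):
        raise CppnCycleError("cycle detected in CPPN graph")

    input_pos = {nid: k for k, nid in enumerate(in_ids)}
    for nid in order:
        node = cppn.nodes[nid]
        if node.role == "input":
            value[nid] = float(x[input_pos[nid]])
            continue
        s = cppn.gene(node, "bias")
        for e in preds[nid]:
            sign = -1.0 if cppn.gene(e, "sign") >= 0.5 else 1.0
            s += sign * cppn.gene(e, "weight") * value[e.source]
        value[nid] = _apply_func(int(cppn.gene(node, "func")), s)
    return np.array([value[nid] for nid in out_ids])


@dataclass
class Substrate:
    """Fixed neuron coordinates in 3D, with role and task labels."""

    coords: np.ndarray           # (n, 3)
    roles: Tuple[str, ...]
    labels: Tuple[Optional[str], ...]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("substrate coordinates must be distinct")

    @property
    def n(self) -> int:
        return len(self.coords)

    def indices(self, role: str) -> List[int]:
        return [i for i, r in enumerate(self.roles) if r == role]


def default_substrate(n_inputs: int = 10) -> Substrate:
    """Inputs on z=-1, hidden on z=0, outputs on z=+1; x evenly spaced on
    [-1, 1] within each semantic group, groups separated in y.

    ``n_inputs=10`` matches the task's input lines (4 stimuli, 2 reward
    lines, 4 feedback); ``n_inputs=9`` is the strict variant with a single
    signed reward line.
    """
    if n_inputs not in (9, 10):
        raise ValueError("n_inputs must be 9 or 10")
    def sym_spaced(n: int) -> np.ndarray:
        # evenly spaced on [-1, 1], exactly antisymmetric in floating point
        xs = np.linspace(-1, 1, n)
        return (xs - xs[::-1]) / 2

    coords, roles, labels = [], [], []
    xs4 = sym_spaced(4)
    for i, x in enumerate(xs4):
        coords.append((x, -0.5, -1.0))
        roles.append("input")
        labels.append(f"stimulus-{i}")
    if n_inputs == 10:
        coords.append((-0.5, 0.0, -1.0)); roles.append("input"); labels.append("reward-pos")
        coords.append((0.5, 0.0, -1.0)); roles.append("input"); labels.append("reward-neg")
    else:
        coords.append((0.0, 0.0, -1.0)); roles.append("input"); labels.append("reward")
    for i, x in enumerate(xs4):
        coords.append((x, 0.5, -1.0))
        roles.append("input")
        labels.append(f"feedback-{i}")
    for x in sym_spaced(5):
        coords.append((x, 0.0, 0.0))
        roles.append("hidden")
        labels.append(None)
    for i, x in enumerate(xs4):
        coords.append((x, 0.0, 1.0))
        roles.append("output")
        labels.append(f"action-{i}")
    return Substrate(np.array(coords), tuple(roles), tuple(labels))


@dataclass
class HnnConfig:
    """leo_threshold: LEO output above it creates the connection;
    modulatory_cutoff: hidden neuron is modulatory iff the node-CPPN kind
    output is below it; weight/bias scales map CPPN outputs onto network
    ranges."""

    leo_threshold: float = 0.5
    modulatory_cutoff: float = 0.4
    bias_scale: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.modulatory_cutoff < 1.0:
            raise ValueError("modulatory_cutoff must be in (0, 1)")


def develop_hnn(
    conn_cppn: GraphGenotype,
    node_cppn: GraphGenotype,
    substrate: Substrate,
    config: Optional[HnnConfig] = None,
    params: Optional[PlasticityParams] = None,
) -> PlasticNetwork:
    """Query the two CPPNs over the substrate to build the network.

    Connectivity is queried for input->hidden, input->output,
    hidden->hidden (self and recurrent included) and hidden->output pairs.
    A constant 1.0 bias input is appended to every CPPN query.
    """
    config = config if config is not None else HnnConfig()
    params = params if params is not None else PlasticityParams()
    if len(conn_cppn.node_ids("input")) != 7 or len(conn_cppn.node_ids("output")) != 2:
        raise ValueError("connection CPPN must have 7 inputs (6 coords + bias) and 2 outputs")
    if len(node_cppn.node_ids("input")) != 4 or len(node_cppn.node_ids("output")) != 2:
        raise ValueError("node CPPN must have 4 inputs (3 coords + bias) and 2 outputs")

    neurons = []
    for i in range(substrate.n):
        bias_out, kind_out = cppn_eval(
            node_cppn, np.append(substrate.coords[i], 1.0)
        )
        role = substrate.roles[i]
        kind = "standard"
        if role == "hidden" and kind_out < config.modulatory_cutoff:
            kind = "modulatory"
        bias = float(np.clip(bias_out, -1.0, 1.0)) * config.bias_scale
        neurons.append(Neuron(i, role, kind, bias, substrate.labels[i]))

    allowed_targets = {"input": ("hidden", "output"), "hidden": ("hidden", "output")}
    conns = []
    for a in range(substrate.n):
        ra = substrate.roles[a]
        if ra not in allowed_targets:
            continue
        for b in range(substrate.n):
            if substrate.roles[b] not in allowed_targets[ra]:
                continue
            query = np.concatenate([substrate.coords[a], substrate.coords[b], [1.0]])
            leo, wout = cppn_eval(conn_cppn, query)
            if leo > config.leo_threshold:
                sign = -1 if wout < 0 else 1
                mag = float(np.clip(abs(wout), 0.0, 1.0)) * params.w_max
                conns.append(Connection(a, b, sign, mag))
    return PlasticNetwork(neurons, conns, params)


@dataclass
class HnnGenotype:
    """Pair of CPPN genotypes (connection-centred, node-centred)."""

    conn: GraphGenotype
    node: GraphGenotype

    def to_dict(self) -> dict:
        return {"conn": self.conn.to_dict(), "node": self.node.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "HnnGenotype":
        return cls(GraphGenotype.from_dict(d["conn"]), GraphGenotype.from_dict(d["node"]))


class HnnEncoding:
    """Encoding interface (random_init / mutate / develop) for HNN."""

    def __init__(
        self,
        substrate: Optional[Substrate] = None,
        config: Optional[HnnConfig] = None,
        rates: Optional[MutationRates] = None,
        params: Optional[PlasticityParams] = None,
    ) -> None:
        self.substrate = substrate if substrate is not None else default_substrate()
        self.config = config if config is not None else HnnConfig()
        self.params = params if params is not None else PlasticityParams()
        self._conn_enc = make_cppn_encoding(7, 2, rates=rates)
        self._node_enc = make_cppn_encoding(4, 2, rates=rates)
        self.rates = self._conn_enc.rates

    def random_init(self, rng: np.random.Generator) -> HnnGenotype:
        return HnnGenotype(
            self._conn_enc.random_init(rng), self._node_enc.random_init(rng)
        )

    def mutate(self, genotype: HnnGenotype, rng: np.random.Generator) -> HnnGenotype:
        return HnnGenotype(
            self._conn_enc.mutate(genotype.conn, rng),
            self._node_enc.mutate(genotype.node, rng),
        )

    def develop(self, genotype: HnnGenotype) -> PlasticNetwork:
        return develop_hnn(
            genotype.conn, genotype.node, self.substrate, self.config, self.params
        )
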
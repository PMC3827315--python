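"""Plastic neuron model: synchronous recurrent networks with neuromodulated
Hebbian plasticity.

Neurons come in two kinds.  *Standard* neurons drive the activation of their
targets through a weighted sum squashed by a steep sigmoid.  *Modulatory*
neurons do not drive activation: the signed, weighted sum of modulatory
inputs at a neuron gates Hebbian changes of the *plastic* weights feeding
that neuron.  A connection is plastic iff its source is standard and its
target receives at least one modulatory input; all other weights are frozen,
because the modulation transfer ``tanh`` vanishes at zero modulation.

Weights are stored as a non-negative magnitude in ``[w_min, w_max]`` plus a
separate excitatory/inhibitory sign; plasticity modifies the magnitude only
and clamps it to the bounds after every update.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

ROLE_INPUT = "input"
ROLE_HIDDEN = "hidden"
ROLE_OUTPUT = "output"
KIND_STANDARD = "standard"
KIND_MODULATORY = "modulatory"

_ROLES = (ROLE_INPUT, ROLE_HIDDEN, ROLE_OUTPUT)
_KINDS = (KIND_STANDARD, KIND_MODULATORY)


class NetworkError(ValueError):
    """Malformed network description."""


class DimensionError(ValueError):
    """Input vector length does not match the number of input neurons."""


@dataclass
class Neuron:
    """A single neuron.

    Parameters
    ----------
    id : hashable
        Unique identifier within the network.
    role : {"input", "hidden", "output"}
    kind : {"standard", "modulatory"}
        Input and output neurons are always standard.
    bias : float
        Added to the weighted sum before the sigmoid.
    label : str, optional
        Free-text semantics, e.g. ``"stimulus-2"`` or ``"reward-pos"``.
    """

    id: object
    role: str = ROLE_HIDDEN
    kind: str = KIND_STANDARD
    bias: float = 0.0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise NetworkError(f"unknown role {self.role!r}")
        if self.kind not in _KINDS:
            raise NetworkError(f"unknown kind {self.kind!r}")
        if self.role == ROLE_INPUT and self.kind == KIND_MODULATORY:
            raise NetworkError("input neurons cannot be modulatory")
        if self.role == ROLE_OUTPUT and self.kind == KIND_MODULATORY:
            raise NetworkError("output neurons must be standard")


@dataclass
class Connection:
    """A signed, weighted, directed connection.

    ``sign`` is +1 (excitatory) or -1 (inhibitory); ``magnitude`` is the
    non-negative weight.  Whether the connection is plastic is derived from
    the kinds of its endpoints, not stored.
    """

    source: object
    target: object
    sign: int = 1
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise NetworkError(f"sign must be +1 or -1, got {self.sign!r}")
        if self.magnitude < 0:
            raise NetworkError("magnitude must be non-negative")


@dataclass
class PlasticityParams:
    """Parameters of the activation and plasticity rules.

    eta : Hebbian learning coefficient (> 0).
    lam : steepness of the activation sigmoid phi(x) = 1/(1+exp(-lam*x)).
    w_min, w_max : weight-magnitude bounds (w_min = 0: no negative weights;
        inhibition is carried by the connection sign).

    The modulation transfer phi_m is tanh: odd, monotone, phi_m(0)=0, range
    (-1, 1), so modulation can both strengthen and weaken weights and
    un-modulated weights stay frozen.
    """

    eta: float = 0.1
    lam: float = 5.0
    w_min: float = 0.0
    w_max: float = 2.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not self.w_min <= self.w_max:
            raise ValueError("w_min must not exceed w_max")

    def phi(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.lam * np.asarray(x, dtype=float)))

    @staticmethod
    def phi_m(x: np.ndarray) -> np.ndarray:
        return np.tanh(x)


class PlasticNetwork:
    """A synchronous recurrent network of plastic neurons.

    All activations at step ``t+1`` are computed from activations at step
    ``t``.  Input neurons relay their clamped values (no sigmoid); clamping
    takes effect immediately, so a feed-forward path of depth ``d`` delivers
    a new input to the output after ``d`` steps.
    """

    def __init__(
        self,
        neurons: Iterable[Neuron],
        connections: Iterable[Connection],
        params: Optional[PlasticityParams] = None,
    ) -> None:
        self.neurons = list(neurons)
        self.connections = list(connections)
        self.params = params if params is not None else PlasticityParams()

        ids = [n.id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate neuron ids")
        self._index = {n.id: i for i, n in enumerate(self.neurons)}
        for c in self.connections:
            if c.source not in self._index or c.target not in self._index:
                raise NetworkError(
                    f"connection {c.source!r}->{c.target!r} references unknown neuron"
                )
        self._rebuild()

    # -- internal compiled arrays ------------------------------------------

    def _rebuild(self) -> None:
        n = len(self.neurons)
        idx = self._index
        self.input_ids = [m.id for m in self.neurons if m.role == ROLE_INPUT]
        self.output_ids = [m.id for m in self.neurons if m.role == ROLE_OUTPUT]
        self._input_idx = np.array([idx[i] for i in self.input_ids], dtype=np.int64)
        self._output_idx = np.array([idx[i] for i in self.output_ids], dtype=np.int64)
        self._bias = np.array([m.bias for m in self.neurons], dtype=float)
        kinds = [m.kind for m in self.neurons]

        e = len(self.connections)
        self._esrc = np.array([idx[c.source] for c in self.connections], dtype=np.int64)
        self._etgt = np.array([idx[c.target] for c in self.connections], dtype=np.int64)
        self._esgn = np.array([c.sign for c in self.connections], dtype=float)
        self._emag = np.array([c.magnitude for c in self.connections], dtype=float)
        self._estd = np.array(
            [kinds[s] == KIND_STANDARD for s in self._esrc], dtype=bool
        )
        modulated = np.zeros(n, dtype=bool)
        for k in range(e):
            if not self._estd[k]:
                modulated[self._etgt[k]] = True
        self._eplastic = self._estd & modulated[self._etgt]

        self._act = np.zeros(n)
        self._mod = np.zeros(n)
        self._stepped = False

    def _write_back(self) -> None:
        for k, c in enumerate(self.connections):
            c.magnitude = float(self._emag[k])

    # -- basic introspection ----------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_inputs(self) -> int:
        return len(self.input_ids)

    @property
    def n_outputs(self) -> int:
        return len(self.output_ids)

    @property
    def activations(self) -> np.ndarray:
        return self._act.copy()

    @property
    def modulatory_sums(self) -> np.ndarray:
        return self._mod.copy()

    @property
    def magnitudes(self) -> np.ndarray:
        return self._emag.copy()

    def plastic_mask(self) -> np.ndarray:
        """Boolean mask over ``connections``: which are plastic."""
        return self._eplastic.copy()

    def output_of(self, neuron_id: object) -> float:
        return float(self._act[self._index[neuron_id]])

    # -- dynamics ----------------------------------------------------------

    def step(self, inputs: Sequence[float]) -> np.ndarray:
        """One synchronous update; returns the full activation vector.

        Also records each neuron's modulatory sum ``m_i`` for the
        subsequent plasticity update.
        """
        x = np.asarray(inputs, dtype=float)
        if x.shape != (self.n_inputs,):
            raise DimensionError(
                f"expected {self.n_inputs} input values, got shape {x.shape}"
            )
        o = self._act
        o[self._input_idx] = x
        contrib = self._esgn * self._emag * o[self._esrc]
        net = self._bias.copy()
        m = np.zeros(self.n_neurons)
        np.add.at(net, self._etgt[self._estd], contrib[self._estd])
        np.add.at(m, self._etgt[~self._estd], contrib[~self._estd])
        new = self.params.phi(net)
        new[self._input_idx] = x
        self._act = new
        self._mod = m
        self._stepped = True
        return new.copy()

    def apply_plasticity(self) -> None:
        """Modulated Hebbian update of the plastic magnitudes.

        dw_ij = eta * tanh(m_i) * o_i * o_j  for plastic j -> i, then clamp
        to [w_min, w_max].  Uses the modulatory sums recorded by the last
        ``step`` and the current (post-step) activations.
        """
        if not self._stepped:
            raise RuntimeError("apply_plasticity requires at least one step() first")
        p = self.params
        mask = self._eplastic
        if mask.any():
            delta = (
                p.eta
                * np.tanh(self._mod[self._etgt[mask]])
                * self._act[self._etgt[mask]]
                * self._act[self._esrc[mask]]
            )
            self._emag[mask] = np.clip(self._emag[mask] + delta, p.w_min, p.w_max)
            self._write_back()

    def activate(
        self, inputs: Sequence[float], n_steps: int, learn: bool = True
    ) -> np.ndarray:
        """Run ``n_steps`` synchronous steps (plasticity after each iff
        ``learn``) and return the output-neuron activations."""
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        for _ in range(n_steps):
            self.step(inputs)
            if learn:
                self.apply_plasticity()
        return self._act[self._output_idx].copy()

    def reset_activations(self) -> None:
        self._act = np.zeros(self.n_neurons)
        self._mod = np.zeros(self.n_neurons)
        self._stepped = False

    def reset_plastic_weights(self, rng: np.random.Generator) -> None:
        """Redraw every plastic magnitude uniformly from [w_min, w_max] and
        zero the activations (start of a lifetime: nothing to un-learn)."""
        u = rng.random(int(self._eplastic.sum()))
        self._reset_plastic_from(u)

    def _reset_plastic_from(self, u: np.ndarray) -> None:
        p = self.params
        self._emag[self._eplastic] = p.w_min + u * (p.w_max - p.w_min)
        self._write_back()
        self.reset_activations()

    # -- structure ---------------------------------------------------------

    def prune_to_io(self) -> "PlasticNetwork":
        """Subnetwork of neurons on some directed input-to-output path.

        Input and output neurons are always kept.  A network with no input
        or no output neurons (e.g. a canonical test graph) is returned
        unchanged.
        """
        if not self.input_ids or not self.output_ids:
            return self.copy()
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self._index)
        g.add_edges_from((c.source, c.target) for c in self.connections)
        fwd: set = set()
        for i in self.input_ids:
            fwd.add(i)
            fwd.update(nx.descendants(g, i))
        bwd: set = set()
        for o in self.output_ids:
            bwd.add(o)
            bwd.update(nx.ancestors(g, o))
        keep = (fwd & bwd) | set(self.input_ids) | set(self.output_ids)
        neurons = [
            Neuron(m.id, m.role, m.kind, m.bias, m.label)
            for m in self.neurons
            if m.id in keep
        ]
        conns = [
            Connection(c.source, c.target, c.sign, c.magnitude)
            for c in self.connections
            if c.source in keep and c.target in keep
        ]
        return PlasticNetwork(neurons, conns, self.params)

    def copy(self) -> "PlasticNetwork":
        return PlasticNetwork(
            [Neuron(m.id, m.role, m.kind, m.bias, m.label) for m in self.neurons],
            [
                Connection(c.source, c.target, c.sign, c.magnitude)
                for c in self.connections
            ],
            PlasticityParams(
                self.params.eta, self.params.lam, self.params.w_min, self.params.w_max
            ),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "neurons": [
                {
                    "id": m.id,
                    "role": m.role,
                    "kind": m.kind,
                    "bias": m.bias,
                    "label": m.label,
                }
                for m in self.neurons
            ],
            "connections": [
                {
                    "source": c.source,
                    "target": c.target,
                    "sign": c.sign,
                    "magnitude": c.magnitude,
                }
                for c in self.connections
            ],
            "params": {
                "eta": self.params.eta,
                "lam": self.params.lam,
                "w_min": self.params.w_min,
                "w_max": self.params.w_max,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlasticNetwork":
        params = PlasticityParams(**d.get("params", {}))
        neurons = [Neuron(**m) for m in d["neurons"]]
        conns = [Connection(**c) for c in d["connections"]]
        return cls(neurons, conns, params)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "PlasticNetwork":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for m in self.neurons:
            g.add_node(m.id, role=m.role, kind=m.kind, bias=m.bias,
                       label=m.label or "")
        for c in self.connections:
            g.add_edge(c.source, c.target, sign=c.sign, magnitude=c.magnitude)
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self) -> str:
        """GraphViz text; excitatory edges red, inhibitory green; inputs
        green, outputs red, modulatory neurons gray, standard hidden blue."""
        node_color = {ROLE_INPUT: "green", ROLE_OUTPUT: "red"}
        lines = ["digraph plastic_network {"]
        for m in self.neurons:
            color = node_color.get(m.role, "gray" if m.kind == KIND_MODULATORY else "blue")
            lab = m.label or str(m.id)
            lines.append(
                f'  "{m.id}" [label="{lab}", color={color}, style=filled];'
            )
        for c in self.connections:
            color = "red" if c.sign > 0 else "green"
            w = max(0.2, c.magnitude)
            lines.append(
                f'  "{c.source}" -> "{c.target}" [color={color}, penwidth={w:.2f}];'
            )
        lines.append("}")
        return "\n".join(lines)
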
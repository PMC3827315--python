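"""Direct graph encoding.

The evolved graph *is* the neural network: nodes map one-to-one to neurons
(intrinsic parameters: standard/modulatory kind and bias) and edges to
signed, weighted connections.  The same machinery, parameterized with an
activation-function gene, encodes the CPPNs of the HNN encoding and the
labeled map-graphs of the map-based encoding (see their modules).

First-generation genotypes are feed-forward input->output nets with random
weights and no hidden nodes, so generation 0 contains no modulatory
neurons and hence no plastic weights.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from ..network import Connection, Neuron, PlasticityParams, PlasticNetwork
from .base import CAT, FLAG, REAL, EdgeGene, GeneSpec, GraphEncoding, GraphGenotype, MutationRates


def task_io_roster(
    n_stimuli: int = 4, n_actions: int = 4, reward_lines: int = 2
) -> List[Tuple[str, str]]:
    """I/O roster in network input order: stimuli, reward line(s), feedback
    (one per action), then the output actions."""
    roster = [("input", f"stimulus-{i}") for i in range(n_stimuli)]
    if reward_lines == 2:
        roster += [("input", "reward-pos"), ("input", "reward-neg")]
    else:
        roster += [("input", "reward")]
    roster += [("input", f"feedback-{i}") for i in range(n_actions)]
    roster += [("output", f"action-{i}") for i in range(n_actions)]
    return roster


class DirectEncoding(GraphEncoding):
    """Direct encoding of a plastic network (or of a CPPN when
    ``n_funcs > 0``).

    Node genes: bias (real), kind (flag: 1 = modulatory, hidden nodes
    only), plus an activation-function selector for CPPNs.  Edge genes:
    weight magnitude (real, non-negative) and sign (flag: 1 = inhibitory).
    """

    def __init__(
        self,
        roster: Optional[List[Tuple[str, str]]] = None,
        rates: Optional[MutationRates] = None,
        bias_bounds: Tuple[float, float] = (-2.0, 2.0),
        weight_bounds: Tuple[float, float] = (0.0, 2.0),
        n_funcs: int = 0,
        params: Optional[PlasticityParams] = None,
    ) -> None:
        super().__init__(rates)
        self._roster = roster if roster is not None else task_io_roster()
        self.bias_bounds = bias_bounds
        self.weight_bounds = weight_bounds
        self.n_funcs = n_funcs
        self.params = params if params is not None else PlasticityParams(
            w_min=weight_bounds[0], w_max=weight_bounds[1]
        )
        node_spec = [
            GeneSpec("bias", REAL, bias_bounds[0], bias_bounds[1], rate="param"),
            GeneSpec("kind", FLAG, rate="param"),
        ]
        if n_funcs > 0:
            node_spec.append(GeneSpec("func", CAT, n_cat=n_funcs, rate="param"))
        self.node_spec = tuple(node_spec)
        self.edge_spec = (
            GeneSpec("weight", REAL, weight_bounds[0], weight_bounds[1], rate="weight"),
            GeneSpec("sign", FLAG, rate="param"),
        )

    def io_roster(self) -> List[Tuple[str, str]]:
        return list(self._roster)

    def develop(self, genotype: GraphGenotype) -> PlasticNetwork:
        """One-to-one mapping of genotype nodes/edges to neurons/connections.

        The modulatory-kind gene is honored for hidden nodes only; I/O
        neurons are forced standard.
        """
        neurons = []
        for nid in genotype.node_ids():
            n = genotype.nodes[nid]
            kind = "standard"
            if n.role == "hidden" and genotype.gene(n, "kind") >= 0.5:
                kind = "modulatory"
            neurons.append(Neuron(nid, n.role, kind, genotype.gene(n, "bias"), n.label))
        conns = [
            Connection(
                e.source,
                e.target,
                -1 if genotype.gene(e, "sign") >= 0.5 else 1,
                genotype.gene(e, "weight"),
            )
            for e in genotype.edges.values()
        ]
        return PlasticNetwork(neurons, conns, self.params)


def cppn_io_roster(n_inputs: int, n_outputs: int, names=None) -> List[Tuple[str, str]]:
    roster = [("input", f"x{i}" if names is None else names[i]) for i in range(n_inputs)]
    roster += [("output", f"out{i}") for i in range(n_outputs)]
    return roster


def make_cppn_encoding(
    n_inputs: int,
    n_outputs: int,
    rates: Optional[MutationRates] = None,
    weight_bounds: Tuple[float, float] = (0.0, 3.0),
    n_funcs: int = 4,
) -> DirectEncoding:
    """Direct encoding configured for CPPN evolution (function gene on
    every node, wider weight range)."""
    return DirectEncoding(
        roster=cppn_io_roster(n_inputs, n_outputs),
        rates=rates,
        weight_bounds=weight_bounds,
        n_funcs=n_funcs,
    )
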
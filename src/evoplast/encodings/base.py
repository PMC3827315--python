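"""Shared graph-genotype machinery.

All three encodings evolve a directed graph whose nodes and edges carry
small real/flag/categorical gene tuples; they differ only in the gene
semantics and in the genotype -> network development.  Mutation is
mutation-only (no crossover) and applies, in fixed order, up to five
structural operators followed by per-element value mutations:

1. add a connection between two random nodes,
2. delete a random connection,
3. move one endpoint of a random connection,
4. add a node by splitting an existing connection (the split edge's genes
   are kept on both halves),
5. delete a random hidden node with its connections,
6. per-connection value mutation (polynomial mutation of real genes),
7. per-node value mutation (polynomial mutation / flag flip / categorical
   redraw of intrinsic parameters).

I/O nodes are never deleted and duplicate edges between the same ordered
pair replace the existing edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

REAL = "real"
FLAG = "flag"
CAT = "cat"


class DevelopmentError(ValueError):
    """Genotype cannot be developed into a well-formed network.

    Surfaced by the evolutionary loop as minimal fitness, not a crash.
    """


@dataclass(frozen=True)
class GeneSpec:
    """Declaration of one gene: name, bounds and mutation behavior.

    ``rate`` selects which per-element mutation probability applies:
    ``"weight"`` (p_weight) or ``"param"`` (p_param).
    """

    name: str
    kind: str = REAL            # real | flag | cat
    lo: float = 0.0
    hi: float = 1.0
    n_cat: int = 0
    rate: str = "param"

    def random(self, rng: np.random.Generator) -> float:
        if self.kind == REAL:
            return float(rng.uniform(self.lo, self.hi))
        if self.kind == FLAG:
            return float(rng.integers(0, 2))
        return float(rng.integers(0, self.n_cat))

    def mutate(self, x: float, eta_m: float, rng: np.random.Generator) -> float:
        if self.kind == REAL:
            return polynomial_mutation(x, self.lo, self.hi, eta_m, rng)
        if self.kind == FLAG:
            return 1.0 - x
        if self.n_cat <= 1:
            return x
        new = int(rng.integers(0, self.n_cat - 1))
        return float(new if new < int(x) else new + 1)


def polynomial_mutation(
    x: float, lo: float, hi: float, eta_m: float, rng: np.random.Generator
) -> float:
    """Deb's bounded polynomial mutation.

    Perturbs ``x`` within ``[lo, hi]``; the distribution index ``eta_m``
    controls the spread (larger -> smaller perturbations).
    """
    if eta_m <= 0:
        raise ValueError("eta_m must be positive")
    if not lo <= x <= hi:
        raise ValueError(f"x={x} outside [{lo}, {hi}]")
    if hi == lo:
        return x
    u = rng.random()
    d1 = (x - lo) / (hi - lo)
    d2 = (hi - x) / (hi - lo)
    mut_pow = 1.0 / (eta_m + 1.0)
    if u < 0.5:
        val = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta_m + 1.0)
        dq = val ** mut_pow - 1.0
    else:
        val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta_m + 1.0)
        dq = 1.0 - val ** mut_pow
    return float(np.clip(x + dq * (hi - lo), lo, hi))


@dataclass
class MutationRates:
    """Per-operator and per-element mutation probabilities."""

    p_add_conn: float = 0.1
    p_del_conn: float = 0.1
    p_move_conn: float = 0.1
    p_add_neuron: float = 0.05
    p_del_neuron: float = 0.05
    p_weight: float = 0.1
    p_param: float = 0.1
    eta_m: float = 15.0

    def __post_init__(self):
        for name in (
            "p_add_conn",
            "p_del_conn",
            "p_move_conn",
            "p_add_neuron",
            "p_del_neuron",
            "p_weight",
            "p_param",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.eta_m <= 0:
            raise ValueError("eta_m must be positive")

    @classmethod
    def zero(cls) -> "MutationRates":
        return cls(0, 0, 0, 0, 0, 0, 0, 15.0)


@dataclass
class NodeGene:
    id: int
    role: str                    # input | hidden | output
    genes: np.ndarray
    label: Optional[str] = None


@dataclass
class EdgeGene:
    source: int
    target: int
    genes: np.ndarray


class GraphGenotype:
    """Directed-graph genotype with typed node/edge gene tuples."""

    def __init__(
        self,
        node_spec: Tuple[GeneSpec, ...],
        edge_spec: Tuple[GeneSpec, ...],
        nodes: Sequence[NodeGene] = (),
        edges: Sequence[EdgeGene] = (),
    ) -> None:
        self.node_spec = tuple(node_spec)
        self.edge_spec = tuple(edge_spec)
        self.nodes: Dict[int, NodeGene] = {}
        self.edges: Dict[Tuple[int, int], EdgeGene] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- structure ---------------------------------------------------------

    def add_node(self, node: NodeGene) -> None:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id}")
        node.genes = np.asarray(node.genes, dtype=float)
        if node.genes.shape != (len(self.node_spec),):
            raise ValueError("node gene vector has wrong length")
        self.nodes[node.id] = node

    def add_edge(self, edge: EdgeGene) -> None:
        """Add an edge; a re-added (source, target) pair replaces."""
        if edge.source not in self.nodes or edge.target not in self.nodes:
            raise ValueError("edge endpoint references unknown node")
        edge.genes = np.asarray(edge.genes, dtype=float)
        if edge.genes.shape != (len(self.edge_spec),):
            raise ValueError("edge gene vector has wrong length")
        self.edges[(edge.source, edge.target)] = edge

    def fresh_id(self) -> int:
        return max(self.nodes, default=-1) + 1

    def node_ids(self, role: Optional[str] = None) -> List[int]:
        if role is None:
            return sorted(self.nodes)
        return sorted(i for i, n in self.nodes.items() if n.role == role)

    def hidden_ids(self) -> List[int]:
        return self.node_ids("hidden")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene(self, obj, name: str) -> float:
        spec = self.node_spec if isinstance(obj, NodeGene) else self.edge_spec
        for k, s in enumerate(spec):
            if s.name == name:
                return float(obj.genes[k])
        raise KeyError(name)

    def copy(self) -> "GraphGenotype":
        g = GraphGenotype(self.node_spec, self.edge_spec)
        for n in self.nodes.values():
            g.add_node(NodeGene(n.id, n.role, n.genes.copy(), n.label))
        for e in self.edges.values():
            g.add_edge(EdgeGene(e.source, e.target, e.genes.copy()))
        return g

    def check_invariants(self) -> None:
        for e in self.edges.values():
            assert e.source in self.nodes and e.target in self.nodes
        for n in self.nodes.values():
            for k, s in enumerate(self.node_spec):
                if s.kind == REAL:
                    assert s.lo <= n.genes[k] <= s.hi, (n.id, s.name, n.genes[k])
        for e in self.edges.values():
            for k, s in enumerate(self.edge_spec):
                if s.kind == REAL:
                    assert s.lo <= e.genes[k] <= s.hi, (e.source, e.target, s.name)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "node_spec": [s.__dict__ for s in self.node_spec],
            "edge_spec": [s.__dict__ for s in self.edge_spec],
            "nodes": [
                {"id": n.id, "role": n.role, "genes": n.genes.tolist(), "label": n.label}
                for n in self.nodes.values()
            ],
            "edges": [
                {"source": e.source, "target": e.target, "genes": e.genes.tolist()}
                for e in self.edges.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GraphGenotype":
        node_spec = tuple(GeneSpec(**s) for s in d["node_spec"])
        edge_spec = tuple(GeneSpec(**s) for s in d["edge_spec"])
        g = cls(node_spec, edge_spec)
        for n in d["nodes"]:
            g.add_node(NodeGene(n["id"], n["role"], np.array(n["genes"]), n.get("label")))
        for e in d["edges"]:
            g.add_edge(EdgeGene(e["source"], e["target"], np.array(e["genes"])))
        return g

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "GraphGenotype":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


class GraphEncoding:
    """Base class: structural + value mutation over GraphGenotype.

    Subclasses declare gene specs, the fixed I/O roster and a
    ``develop(genotype) -> PlasticNetwork`` mapping.
    """

    node_spec: Tuple[GeneSpec, ...]
    edge_spec: Tuple[GeneSpec, ...]

    def __init__(self, rates: Optional[MutationRates] = None) -> None:
        self.rates = rates if rates is not None else MutationRates()

    # roster: list of (role, label) in network input order then output order
    def io_roster(self) -> List[Tuple[str, str]]:
        raise NotImplementedError

    def develop(self, genotype: GraphGenotype):
        raise NotImplementedError

    # -- initialization ----------------------------------------------------

    def _random_genes(self, spec, rng) -> np.ndarray:
        return np.array([s.random(rng) for s in spec])

    def random_init(self, rng: np.random.Generator) -> GraphGenotype:
        """First-generation genotype: feed-forward, no hidden nodes, every
        input connected to every output with random genes."""
        g = GraphGenotype(self.node_spec, self.edge_spec)
        roster = self.io_roster()
        for i, (role, label) in enumerate(roster):
            g.add_node(NodeGene(i, role, self._random_genes(self.node_spec, rng), label))
        for i in g.node_ids("input"):
            for o in g.node_ids("output"):
                g.add_edge(EdgeGene(i, o, self._random_genes(self.edge_spec, rng)))
        return g

    # -- mutation ----------------------------------------------------------

    def mutate(self, genotype: GraphGenotype, rng: np.random.Generator) -> GraphGenotype:
        g = genotype.copy()
        r = self.rates
        if rng.random() < r.p_add_conn:
            self._add_connection(g, rng)
        if rng.random() < r.p_del_conn:
            self._del_connection(g, rng)
        if rng.random() < r.p_move_conn:
            self._move_connection(g, rng)
        if rng.random() < r.p_add_neuron:
            self._add_neuron(g, rng)
        if rng.random() < r.p_del_neuron:
            self._del_neuron(g, rng)
        self._mutate_values(g, rng)
        return g

    @staticmethod
    def _pick(seq, rng):
        return seq[int(rng.integers(0, len(seq)))]

    def _valid_targets(self, g: GraphGenotype) -> List[int]:
        return g.node_ids("hidden") + g.node_ids("output")

    def _add_connection(self, g, rng) -> None:
        src = self._pick(g.node_ids(), rng)
        tgt = self._pick(self._valid_targets(g), rng)
        g.add_edge(EdgeGene(src, tgt, self._random_genes(self.edge_spec, rng)))

    def _del_connection(self, g, rng) -> None:
        if not g.edges:
            return
        key = self._pick(sorted(g.edges), rng)
        del g.edges[key]

    def _move_connection(self, g, rng) -> None:
        if not g.edges:
            return
        key = self._pick(sorted(g.edges), rng)
        edge = g.edges.pop(key)
        if rng.random() < 0.5:
            edge = EdgeGene(self._pick(g.node_ids(), rng), edge.target, edge.genes)
        else:
            edge = EdgeGene(edge.source, self._pick(self._valid_targets(g), rng), edge.genes)
        g.edges[(edge.source, edge.target)] = edge

    def _add_neuron(self, g, rng) -> None:
        """Split a random connection; both halves keep the split edge's
        genes (weight preserved on the two connections)."""
        if not g.edges:
            return
        key = self._pick(sorted(g.edges), rng)
        edge = g.edges.pop(key)
        nid = g.fresh_id()
        g.add_node(NodeGene(nid, "hidden", self._random_genes(self.node_spec, rng)))
        g.add_edge(EdgeGene(edge.source, nid, edge.genes.copy()))
        g.add_edge(EdgeGene(nid, edge.target, edge.genes.copy()))

    def _del_neuron(self, g, rng) -> None:
        hidden = g.hidden_ids()
        if not hidden:
            return
        nid = self._pick(hidden, rng)
        del g.nodes[nid]
        for key in [k for k in g.edges if nid in k]:
            del g.edges[key]

    def _mutate_values(self, g, rng) -> None:
        r = self.rates
        for e in g.edges.values():
            for k, s in enumerate(self.edge_spec):
                p = r.p_weight if s.rate == "weight" else r.p_param
                if rng.random() < p:
                    e.genes[k] = s.mutate(float(e.genes[k]), r.eta_m, rng)
        for n in g.nodes.values():
            for k, s in enumerate(self.node_spec):
                p = r.p_weight if s.rate == "weight" else r.p_param
                if rng.random() < p:
                    n.genes[k] = s.mutate(float(n.genes[k]), r.eta_m, rng)
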
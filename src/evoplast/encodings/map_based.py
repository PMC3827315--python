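"""Map-based developmental encoding.

The genotype is a small labeled graph whose nodes are either single
neurons or *neural maps* (groups of ``map_size`` identical neurons, as in
computational-neuroscience models of spatially organized populations) and
whose edges carry a connection scheme: one-to-one (the k-th source neuron
to the k-th target neuron) or one-to-all, with a uniform synaptic weight
and an excitatory/inhibitory flag.  Every label is a real gene in [0, 1];
booleans are read off by thresholding at 0.5 and the weight is scaled
affinely to the network weight range.

Because a map's neurons are expanded identically, developed networks are
strongly biased towards regular structure: a hidden map whose edges are
all one-to-all contributes a full ``map_size!`` factor of automorphisms.

The labeled graph itself is evolved with the direct-encoding operators.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from ..network import Connection, Neuron, PlasticityParams, PlasticNetwork
from .base import (
    REAL,
    DevelopmentError,
    GeneSpec,
    GraphEncoding,
    GraphGenotype,
    MutationRates,
)


def decode_bool(gene: float) -> bool:
    """Threshold decoding of a boolean label gene."""
    if not 0.0 <= gene <= 1.0:
        raise ValueError(f"label gene {gene} outside [0, 1]")
    return bool(gene >= 0.5)


def decode_affine(gene: float, lo: float, hi: float) -> float:
    if not 0.0 <= gene <= 1.0:
        raise ValueError(f"label gene {gene} outside [0, 1]")
    return lo + gene * (hi - lo)


def decode_labels(
    node_or_edge_genes: np.ndarray,
    kind: str,
    w_max: float = 2.0,
    bias_bounds: Tuple[float, float] = (-2.0, 2.0),
) -> Dict[str, object]:
    """Decode a raw gene vector into semantic labels.

    ``kind`` is "node" (is_map, inhibitory, modulatory, bias) or "edge"
    (weight, inhibitory, connection_type).  Total and idempotent on
    [0, 1]-valued genes; raises for out-of-range genes.
    """
    g = np.asarray(node_or_edge_genes, dtype=float)
    if kind == "node":
        return {
            "is_map": decode_bool(g[0]),
            "inhibitory": decode_bool(g[1]),
            "modulatory": decode_bool(g[2]),
            "bias": decode_affine(g[3], *bias_bounds),
        }
    if kind == "edge":
        return {
            "weight": decode_affine(g[0], 0.0, w_max),
            "inhibitory": decode_bool(g[1]),
            "connection_type": "one_to_all" if decode_bool(g[2]) else "one_to_one",
        }
    raise ValueError(f"kind must be 'node' or 'edge', got {kind!r}")


class MapDevelopmentConfig:
    """map_size: number of neurons per map (identical for all maps)."""

    def __init__(self, map_size: int = 4):
        if map_size < 1:
            raise ValueError("map_size must be >= 1")
        self.map_size = map_size


# Fixed genotype I/O roster (network input order is stimulus map, the two
# reward singletons, feedback map; outputs are one action map).
_STIM, _RPOS, _RNEG, _FB, _OUT = range(5)


class MapEncoding(GraphEncoding):
    """Labeled map-graph genotype -> plastic network."""

    node_spec = (
        GeneSpec("is_map", REAL, 0.0, 1.0, rate="param"),
        GeneSpec("inhibitory", REAL, 0.0, 1.0, rate="param"),
        GeneSpec("kind", REAL, 0.0, 1.0, rate="param"),
        GeneSpec("bias", REAL, 0.0, 1.0, rate="param"),
    )
    edge_spec = (
        GeneSpec("weight", REAL, 0.0, 1.0, rate="weight"),
        GeneSpec("inhibitory", REAL, 0.0, 1.0, rate="param"),
        GeneSpec("conn_type", REAL, 0.0, 1.0, rate="param"),
    )

    def __init__(
        self,
        config: Optional[MapDevelopmentConfig] = None,
        rates: Optional[MutationRates] = None,
        bias_bounds: Tuple[float, float] = (-2.0, 2.0),
        params: Optional[PlasticityParams] = None,
    ) -> None:
        super().__init__(rates)
        self.config = config if config is not None else MapDevelopmentConfig()
        self.bias_bounds = bias_bounds
        self.params = params if params is not None else PlasticityParams()

    def io_roster(self) -> List[Tuple[str, str]]:
        return [
            ("input", "stimulus-map"),
            ("input", "reward-pos"),
            ("input", "reward-neg"),
            ("input", "feedback-map"),
            ("output", "action-map"),
        ]

    # forced development semantics of the I/O roster
    _IO_IS_MAP = {_STIM: True, _RPOS: False, _RNEG: False, _FB: True, _OUT: True}
    _IO_LABELS = {
        _STIM: "stimulus-{k}",
        _RPOS: "reward-pos",
        _RNEG: "reward-neg",
        _FB: "feedback-{k}",
        _OUT: "action-{k}",
    }

    def _node_semantics(self, genotype: GraphGenotype, nid: int):
        node = genotype.nodes[nid]
        labels = decode_labels(
            node.genes, "node", self.params.w_max, self.bias_bounds
        )
        if nid in self._IO_IS_MAP:
            labels["is_map"] = self._IO_IS_MAP[nid]
            labels["modulatory"] = False  # inputs cannot be modulatory; outputs standard
        return node, labels

    def develop(self, genotype: GraphGenotype) -> PlasticNetwork:
        """Expand the labeled graph into a full network.

        Deterministic and total on valid genotypes: each map node becomes
        ``map_size`` identical neurons, each singleton one neuron;
        one-to-one edges pair same-index neurons (a singleton on either
        end degenerates to one-to-all), one-to-all edges form the full
        bipartite pattern, all with the edge's uniform weight and sign.
        """
        msize = self.config.map_size
        members: Dict[int, List[str]] = {}
        neurons: List[Neuron] = []

        def expand(nid: int):
            node, labels = self._node_semantics(genotype, nid)
            count = msize if labels["is_map"] else 1
            kind = "modulatory" if (node.role == "hidden" and labels["modulatory"]) else "standard"
            ids = []
            for k in range(count):
                mid = f"n{nid}.{k}"
                lab = None
                if nid in self._IO_LABELS:
                    lab = self._IO_LABELS[nid].format(k=k)
                neurons.append(Neuron(mid, node.role, kind, labels["bias"], lab))
                ids.append(mid)
            members[nid] = ids

        for nid in (_STIM, _RPOS, _RNEG, _FB):
            expand(nid)
        for nid in genotype.hidden_ids():
            expand(nid)
        expand(_OUT)

        conns: List[Connection] = []
        for e in genotype.edges.values():
            elab = decode_labels(e.genes, "edge", self.params.w_max)
            _, src_labels = self._node_semantics(genotype, e.source)
            sign = -1 if (elab["inhibitory"] or src_labels["inhibitory"]) else 1
            w = elab["weight"]
            src, tgt = members[e.source], members[e.target]
            if elab["connection_type"] == "one_to_one" and len(src) > 1 and len(tgt) > 1:
                if len(src) != len(tgt):
                    raise DevelopmentError(
                        f"one-to-one between maps of sizes {len(src)} and {len(tgt)}"
                    )
                pairs = zip(src, tgt)
            else:
                pairs = ((a, b) for a in src for b in tgt)
            for a, b in pairs:
                conns.append(Connection(a, b, sign, w))
        return PlasticNetwork(neurons, conns, self.params)

    def has_free_hidden_map(
        self, genotype: GraphGenotype, network: Optional[PlasticNetwork] = None
    ) -> bool:
        """True if some hidden map node is *free*: all its incident edges
        are one-to-all and all its developed neurons survive pruning.

        The neurons of a free hidden map are mutually interchangeable, so
        the developed network's automorphism count is guaranteed to be a
        multiple of ``map_size!``.
        """
        network = network if network is not None else self.develop(genotype)
        kept = {m.id for m in network.prune_to_io().neurons}
        for nid in genotype.hidden_ids():
            _, labels = self._node_semantics(genotype, nid)
            if not labels["is_map"]:
                continue
            incident = [
                e for e in genotype.edges.values() if nid in (e.source, e.target)
            ]
            if not incident:
                continue  # fully isolated map is pruned away
            if any(
                decode_labels(e.genes, "edge")["connection_type"] != "one_to_all"
                for e in incident
            ):
                continue
            members = {f"n{nid}.{k}" for k in range(self.config.map_size)}
            if members <= kept:
                return True
        return False
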
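"""Network regularity as the exact number of graph automorphisms.

A network is first pruned to its input/output-connected core, then turned
into a vertex-colored directed graph: neurons become vertices colored "m"
(modulatory) or "n" (all others), and each signed weighted connection is
replaced by a two-edge path through an auxiliary vertex colored by the
weight's bin (large/small x negative/positive), which folds the edge
labels into vertex colors.  Biases are ignored.  The number of
color-preserving automorphisms of this graph (>= 1: the identity) counts
the network's structural symmetries; a count of ``k!`` signals a
sub-structure repeated ``k`` times.

Counting delegates to the exact BLISS engine (via python-igraph) for the
group generators and to a Schreier-Sims computation (sympy) for the group
order, so arbitrarily large symmetry groups are counted without
enumeration.  A brute-force enumerator over color-respecting vertex
permutations serves as an independent oracle for small graphs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import PlasticNetwork

COLOR_MODULATORY = "m"
COLOR_STANDARD = "n"
BIN_COLORS = ("large_negative", "small_negative", "small_positive", "large_positive")


@dataclass
class WeightBins:
    """Four-way binning of signed weights.

    ``boundary`` splits small from large magnitudes (default w_max/2);
    weight 0 falls in "small_positive" (tie-break convention).
    """

    boundary: float = 1.0

    def __post_init__(self):
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")


def bin_weight(signed_weight: float, bins: WeightBins) -> str:
    large = abs(signed_weight) >= bins.boundary
    positive = signed_weight >= 0
    if positive:
        return "large_positive" if large else "small_positive"
    return "large_negative" if large else "small_negative"


@dataclass
class ColoredGraph:
    """Vertex-colored directed graph."""

    colors: List[str]
    edges: List[Tuple[int, int]]

    @property
    def n(self) -> int:
        return len(self.colors)

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph(n=self.n, edges=self.edges, directed=True)
        palette = {c: k for k, c in enumerate(sorted(set(self.colors)))}
        return g, [palette[c] for c in self.colors]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for v, c in enumerate(self.colors):
            g.add_node(v, color=c)
        g.add_edges_from(self.edges)
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def to_dimacs(self) -> str:
        """DIMACS-like text: one ``v <vertex> <color>`` line per vertex and
        one ``e <src> <tgt>`` line per directed edge (1-based)."""
        palette = {c: k for k, c in enumerate(sorted(set(self.colors)))}
        lines = [f"p edge {self.n} {len(self.edges)}"]
        lines += [f"v {v + 1} {palette[c]}" for v, c in enumerate(self.colors)]
        lines += [f"e {a + 1} {b + 1}" for a, b in self.edges]
        return "\n".join(lines)


def to_colored_graph(
    network: PlasticNetwork,
    bins: Optional[WeightBins] = None,
    plastic_mode: str = "midpoint",
    prune: bool = True,
) -> ColoredGraph:
    """Transform a network into its regularity graph.

    ``plastic_mode="midpoint"`` (default) sets every plastic magnitude to
    (w_min + w_max)/2 before binning, so the measure is deterministic and
    independent of learning history; ``"snapshot"`` bins the current
    magnitudes instead.
    """
    if plastic_mode not in ("midpoint", "snapshot"):
        raise ValueError("plastic_mode must be 'midpoint' or 'snapshot'")
    if bins is None:
        bins = WeightBins(boundary=network.params.w_max / 2.0)
    net = network.prune_to_io() if prune else network
    index = {m.id: k for k, m in enumerate(net.neurons)}
    colors = [
        COLOR_MODULATORY if m.kind == "modulatory" else COLOR_STANDARD
        for m in net.neurons
    ]
    edges: List[Tuple[int, int]] = []
    plastic = net.plastic_mask()
    midpoint = (net.params.w_min + net.params.w_max) / 2.0
    for k, c in enumerate(net.connections):
        mag = midpoint if (plastic_mode == "midpoint" and plastic[k]) else c.magnitude
        v = len(colors)
        colors.append(bin_weight(c.sign * mag, bins))
        edges.append((index[c.source], v))
        edges.append((v, index[c.target]))
    return ColoredGraph(colors, edges)


def count_automorphisms(graph: ColoredGraph) -> int:
    """Exact automorphism count via BLISS generators + group order."""
    if graph.n == 0:
        return 1
    g, colors = graph.to_igraph()
    generators = g.automorphism_group(color=colors)
    if not generators:
        return 1
    from sympy.combinatorics import Permutation, PermutationGroup

    perms = [Permutation(list(p), size=graph.n) for p in generators]
    return int(PermutationGroup(perms).order())


def count_automorphisms_vf2(graph: ColoredGraph) -> int:
    """Independent exact count by VF2 enumeration (small graphs only)."""
    g, colors = graph.to_igraph()
    return int(g.count_automorphisms_vf2(color=colors))


def brute_force_automorphisms(
    graph: ColoredGraph,
    edge_colors: Optional[Dict[Tuple[int, int], str]] = None,
    max_vertices: int = 10,
) -> int:
    """Count automorphisms by enumerating color-respecting permutations.

    Only permutations mapping each color class onto itself are generated.
    ``edge_colors`` optionally labels edges; an automorphism must then
    also preserve edge labels (used to check edge-labeled graphs directly,
    without the bin-vertex transform).  Refuses graphs with more than
    ``max_vertices`` vertices.
    """
    n = graph.n
    if n > max_vertices:
        raise ValueError(f"brute force limited to {max_vertices} vertices, got {n}")
    if n == 0:
        return 1
    classes: Dict[str, List[int]] = {}
    for v, c in enumerate(graph.colors):
        classes.setdefault(c, []).append(v)
    edge_set = set(graph.edges)
    if edge_colors is None:
        labeled = {e: None for e in edge_set}
    else:
        labeled = {e: edge_colors.get(e) for e in edge_set}

    count = 0
    class_lists = list(classes.values())
    for perm_parts in itertools.product(
        *(itertools.permutations(c) for c in class_lists)
    ):
        pi = [0] * n
        for orig, img in zip(class_lists, perm_parts):
            for a, b in zip(orig, img):
                pi[a] = b
        ok = True
        for (a, b), lab in labeled.items():
            image = (pi[a], pi[b])
            if image not in edge_set or labeled[image] != lab:
                ok = False
                break
        if ok:
            count += 1
    return count


def network_automorphisms(
    network: PlasticNetwork,
    bins: Optional[WeightBins] = None,
    plastic_mode: str = "midpoint",
) -> int:
    """Convenience: transform and count in one call."""
    return count_automorphisms(to_colored_graph(network, bins, plastic_mode))
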
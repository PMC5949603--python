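"""Residue-anonymous bicyclic peptide topologies: classification, enumeration,
and chemical-space counting.

A bicyclic peptide graph (cyclomatic number 2) whose ring system has two
degree-3 bridgehead nodes joined by three node-disjoint bridges of sizes
a >= b >= c (non-bridgehead residues per bridge) is written
``bicyclo[a.b.c]`` by analogy with bridged bicycloalkanes; ``c >= 1`` is
a bridged system, ``c = 0`` a fused (edge-sharing) one. The ring residue
count is n = a + b + c + 2.

Sequence-space counts are reported per configuration (alphabet size,
node-role restriction, symmetry handling) rather than as a single
number: the enumeration rules behind published headline counts for this
compound class are not uniquely determined by the topology definition
alone, so the module exposes the knobs and reports counts side by side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Tuple

import networkx as nx

__all__ = [
    "Topology",
    "EnumerationConfig",
    "TopologyError",
    "classify_graph",
    "enumerate_topologies",
    "count_sequences",
    "bicyclo_descriptor",
    "realize_topology",
    "partitions_exact",
]


class TopologyError(ValueError):
    """Graph shape unsupported for the bicyclo[a.b.c] descriptor."""


@dataclass(frozen=True, order=True)
class Topology:
    """Canonical bridge decomposition, sizes sorted a >= b >= c."""

    a: int
    b: int
    c: int
    pendant_residues: int = 0

    def __post_init__(self):
        if not (self.a >= self.b >= self.c >= 0):
            raise ValueError("bridge sizes must satisfy a >= b >= c >= 0")

    @property
    def bridges(self) -> Tuple[int, int, int]:
        return (self.a, self.b, self.c)

    @property
    def ring_residues(self) -> int:
        return self.a + self.b + self.c + 2

    @property
    def topology_class(self) -> Literal["bridged", "fused"]:
        return "bridged" if self.c >= 1 else "fused"

    @property
    def descriptor(self) -> str:
        return f"bicyclo[{self.a}.{self.b}.{self.c}]"


def bicyclo_descriptor(t: Topology) -> str:
    """``bicyclo[a.b.c]`` descriptor string."""
    return t.descriptor


def classify_graph(g: nx.MultiGraph) -> Topology:
    """Bridge decomposition of a bicyclic multigraph.

    Pendant trees are stripped to reach the ring system (the 2-core);
    stripped nodes are counted as pendant residues. The ring system must
    have exactly two degree-3 nodes (the bridgeheads) and no node of
    degree > 3; spiro systems (a degree-4 node) are rejected.
    """
    if not nx.is_connected(nx.Graph(g)):
        raise TopologyError("graph is not connected")
    cyclomatic = g.number_of_edges() - g.number_of_nodes() + 1
    if cyclomatic != 2:
        raise TopologyError(f"graph is not bicyclic (cyclomatic {cyclomatic})")

    core = g.copy()
    pendants = 0
    while True:
        leaves = [v for v in core if core.degree(v) <= 1]
        if not leaves:
            break
        core.remove_nodes_from(leaves)
        pendants += len(leaves)

    degrees = dict(core.degree())
    if any(d > 3 for d in degrees.values()):
        raise TopologyError("node of degree > 3 in the ring system (spiro/unsupported)")
    bridgeheads = [v for v, d in degrees.items() if d == 3]
    if len(bridgeheads) != 2:
        raise TopologyError(
            f"expected 2 degree-3 bridgeheads, found {len(bridgeheads)}"
        )
    u, v = bridgeheads

    # Bridge sizes: components left after deleting the bridgeheads, plus
    # one size-0 bridge per direct u-v edge.
    rest = core.copy()
    rest.remove_nodes_from([u, v])
    sizes = [len(comp) for comp in nx.connected_components(rest)]
    sizes += [0] * core.number_of_edges(u, v)
    if len(sizes) != 3:
        raise TopologyError(f"expected 3 bridges, found {len(sizes)}")
    a, b, c = sorted(sizes, reverse=True)
    return Topology(a, b, c, pendant_residues=pendants)


@dataclass
class EnumerationConfig:
    """Knobs for topology enumeration and sequence counting.

    max_residues      largest ring residue count n (default 15)
    classes           which ring classes to include
    min_bridge        lower bound on the smallest bridge (1 for bridged,
                      0 admits fused); derived from ``classes`` when None
    alphabet_size     residues available per non-bridgehead node
    branch_alphabet_size
                      residues available per bridgehead node (diamino
                      acids / amino diacids); None = same as alphabet_size
    symmetry          'raw' counts every labeled assignment;
                      'automorphism' applies Burnside's lemma over the
                      topology graph automorphisms
    orientations      additionally count C->N orientation classes, a
                      factor 2 per bridge with at least one residue
    """

    max_residues: int = 15
    classes: Tuple[str, ...] = ("bridged",)
    alphabet_size: int = 20
    branch_alphabet_size: Optional[int] = None
    symmetry: Literal["raw", "automorphism"] = "raw"
    orientations: bool = False

    def min_c(self) -> int:
        return 0 if "fused" in self.classes else 1


def partitions_exact(total: int, parts: int) -> List[Tuple[int, ...]]:
    """Partitions of ``total`` into exactly ``parts`` positive parts,
    each partition non-increasing."""
    out: List[Tuple[int, ...]] = []

    def rec(remaining: int, k: int, maximum: int, acc: Tuple[int, ...]):
        if k == 0:
            if remaining == 0:
                out.append(acc)
            return
        for first in range(min(remaining - k + 1, maximum), 0, -1):
            rec(remaining - first, k - 1, first, acc + (first,))

    rec(total, parts, total, ())
    return out


def enumerate_topologies(cfg: EnumerationConfig) -> List[Topology]:
    """All canonical topologies with ring count <= cfg.max_residues,
    sorted by (n, a, b, c)."""
    seen = set()
    out: List[Topology] = []
    for n in range(3, cfg.max_residues + 1):
        interior = n - 2
        if "bridged" in cfg.classes:
            for a, b, c in partitions_exact(interior, 3):
                t = Topology(a, b, c)
                if t not in seen:
                    seen.add(t)
                    out.append(t)
        if "fused" in cfg.classes:
            for a, b in partitions_exact(interior, 2):
                t = Topology(a, b, 0)
                if t not in seen:
                    seen.add(t)
                    out.append(t)
    out.sort(key=lambda t: (t.ring_residues, t.a, t.b, t.c))
    return out


def _topology_graph(t: Topology) -> nx.MultiGraph:
    g = nx.MultiGraph()
    u, v = "bh1", "bh2"
    g.add_nodes_from([u, v])
    for bi, size in enumerate(t.bridges):
        if size == 0:
            g.add_edge(u, v)
            continue
        prev = u
        for k in range(size):
            node = (bi, k)
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, v)
    return g


def _automorphisms(g: nx.MultiGraph):
    gm = nx.algorithms.isomorphism.MultiGraphMatcher(g, g)
    return list(gm.isomorphisms_iter())


def _cycle_index_count(t: Topology, alpha: int, beta: int) -> int:
    """Burnside count of node colorings of the topology graph with
    ``alpha`` colors on bridge nodes and ``beta`` on bridgeheads."""
    g = _topology_graph(t)
    autos = _automorphisms(g)
    total = 0
    for perm in autos:
        visited = set()
        cyc_bridge = cyc_bh = 0
        for node in g.nodes:
            if node in visited:
                continue
            cur = node
            while cur not in visited:
                visited.add(cur)
                cur = perm[cur]
            if isinstance(node, str):
                cyc_bh += 1
            else:
                cyc_bridge += 1
        # permutation cycles never mix bridgeheads with bridge nodes
        # (degree is preserved), so the product factorizes
        total += alpha**cyc_bridge * beta**cyc_bh
    return total // len(autos)


def count_sequences(
    topologies: Iterable[Topology], cfg: EnumerationConfig
) -> int:
    """Total sequence count over the given topologies (exact big integer).

    Raw mode: alphabet^(bridge nodes) x branch_alphabet^2 per topology.
    Automorphism mode: Burnside-corrected count of colorings unique up to
    a graph automorphism of the topology.
    """
    topologies = list(topologies)
    if not topologies:
        raise ValueError("no topologies to count")
    alpha = cfg.alphabet_size
    beta = cfg.branch_alphabet_size if cfg.branch_alphabet_size is not None else alpha
    total = 0
    for t in topologies:
        if cfg.symmetry == "raw":
            count = alpha ** (t.ring_residues - 2) * beta**2
        else:
            count = _cycle_index_count(t, alpha, beta)
        if cfg.orientations:
            count *= 2 ** sum(1 for s in t.bridges if s >= 1)
        total += count
    return total


def realize_topology(t: Topology) -> "PeptideGraph":  # noqa: F821
    """A glycine :class:`~bbpkit.notation.PeptideGraph` realizing ``t``.

    The chain is laid out as bridge-b, bridgehead, bridge-a, bridgehead,
    bridge-c, with closures (chain head -> second bridgehead) and (first
    bridgehead -> chain tail), the layout used by the double-lactam
    synthesis. Bond chemistry is nominal (lactam) since only the graph
    shape matters here.
    """
    from bbpkit.notation import BondRecord, PeptideGraph, Residue

    a, b, c = t.bridges
    n = a + b + c + 2
    residues = [
        Residue(code="G", chirality="achiral", base_type="G", position=i + 1)
        for i in range(n)
    ]
    bonds = [BondRecord(i, i + 1, "backbone_amide") for i in range(1, n)]
    u = b + 1  # first bridgehead
    v = b + a + 2  # second bridgehead
    bonds.append(BondRecord(1, v, "sidechain_lactam"))
    bonds.append(BondRecord(u, n, "sidechain_lactam"))
    return PeptideGraph(residues=residues, bonds=bonds)
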
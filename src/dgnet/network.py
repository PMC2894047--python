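"""Graph data model, file I/O and elementary operations.

The interactome is modeled as a simple undirected, unweighted graph whose
nodes are gene identifiers.  Identifiers are opaque strings upper-cased at
ingest; no symbol-alias resolution is attempted (identifier mapping is an
upstream concern).  Self-loops are dropped and duplicate edges collapsed,
so the degree sum always equals twice the edge count.

Supported file formats: two-column edge lists (whitespace-delimited,
``#`` comments), SIF (node, relation, targets; the relation is ignored)
and GraphML (used for round-tripping annotated subnetworks).  Writers emit
nodes and edges in lexicographic order so output is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Network",
    "GeneSet",
    "NetworkFormatError",
    "normalize_gene",
    "read_network",
    "write_edge_list",
    "write_graphml",
    "read_gene_set",
    "write_gene_set",
    "map_gene_set",
    "degree",
    "shortest_path_lengths",
    "clustering_coefficient",
    "induced_subgraph",
    "largest_connected_component",
]


class NetworkFormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared dialect."""


def normalize_gene(gene: object) -> str:
    """Upper-cased, stripped string form of a gene identifier."""
    return str(gene).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (members are case-normalized)."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[object]) -> "GeneSet":
        members = frozenset(
            normalize_gene(g) for g in genes if str(g).strip()
        )
        return cls(name=name, members=members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: object) -> bool:
        return normalize_gene(gene) in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


class Network:
    """Simple undirected graph of upper-cased gene identifiers.

    Wraps a :class:`networkx.Graph`; all mutation goes through
    :meth:`from_edges` so the invariants (no self-loops, no duplicate
    edges, every endpoint a node) hold by construction.
    """

    __slots__ = ("graph", "name", "n_self_loops_dropped", "n_duplicates_dropped")

    def __init__(self, graph: nx.Graph | None = None, name: str = "network"):
        self.graph = graph if graph is not None else nx.Graph()
        self.name = name
        self.n_self_loops_dropped = 0
        self.n_duplicates_dropped = 0

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[object, object]],
        nodes: Iterable[object] = (),
        name: str = "network",
    ) -> "Network":
        g = nx.Graph()
        for n in nodes:
            g.add_node(normalize_gene(n))
        loops = dups = 0
        for u, v in edges:
            u, v = normalize_gene(u), normalize_gene(v)
            if u == v:
                loops += 1
                continue
            if g.has_edge(u, v):
                dups += 1
                continue
            g.add_edge(u, v)
        net = cls(g, name=name)
        net.n_self_loops_dropped = loops
        net.n_duplicates_dropped = dups
        return net

    # -- basic views -------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def has_node(self, gene: object) -> bool:
        return normalize_gene(gene) in self.graph

    def __contains__(self, gene: object) -> bool:
        return self.has_node(gene)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network({self.name!r}, n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError on breach."""
        g = self.graph
        assert nx.number_of_selfloops(g) == 0, "self-loop present"
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()
        for u, v in g.edges:
            assert u in g and v in g


# -- file readers ----------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".sif":
        return "sif"
    if suffix == ".graphml":
        return "graphml"
    return "edge-list"


def read_network(path: str | Path, format: str | None = None, name: str | None = None) -> Network:
    """Read a network file (edge-list, SIF or GraphML) into a :class:`Network`.

    Self-loops and duplicate edges are dropped (counts retained on the
    returned object); identifiers are upper-cased.  Raises
    :class:`NetworkFormatError` naming the offending line for malformed
    input and for an empty graph.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    label = name or path.stem
    if fmt == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # lxml / xml parse failures
            raise NetworkFormatError(f"{path}: not valid GraphML: {exc}") from exc
        net = Network.from_edges(g.edges(), nodes=g.nodes(), name=label)
    elif fmt in ("edge-list", "edgelist", "edges"):
        net = _read_edge_list(path, label)
    elif fmt == "sif":
        net = _read_sif(path, label)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
    if net.n_nodes == 0:
        raise NetworkFormatError(f"{path}: empty graph")
    return net


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _read_edge_list(path: Path, name: str) -> Network:
    edges = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected two identifier columns, got {line!r}"
            )
        edges.append((fields[0], fields[1]))
    return Network.from_edges(edges, name=name)


def _read_sif(path: Path, name: str) -> Network:
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            nodes.append(fields[0])  # isolated node
        elif len(fields) >= 3:
            src = fields[0]
            edges.extend((src, tgt) for tgt in fields[2:])
        else:
            raise NetworkFormatError(
                f"{path}:{lineno}: SIF line needs 1 or >=3 fields, got {line!r}"
            )
    return Network.from_edges(edges, nodes=nodes, name=name)


# -- file writers ----------------------------------------------------------


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a two-column tab-delimited edge list, lexicographically sorted."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in net.sorted_edges():
            fh.write(f"{u}\t{v}\n")
        for n in net.sorted_nodes():
            if net.graph.degree(n) == 0:
                fh.write(f"{n}\n")


def write_graphml(
    net: Network,
    path: str | Path,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write GraphML with deterministic node/edge order.

    ``node_attrs`` maps attribute name -> {node: value}; missing nodes get
    no attribute.  Used to annotate subnetworks (set membership, degree,
    GWAS p-values) for plotting tools.
    """
    g = nx.Graph()
    for n in net.sorted_nodes():
        g.add_node(n)
    for u, v in net.sorted_edges():
        g.add_edge(u, v)
    if node_attrs:
        for attr in sorted(node_attrs):
            mapping = node_attrs[attr]
            for node in sorted(mapping):
                if node in g:
                    g.nodes[node][attr] = mapping[node]
    nx.write_graphml(g, str(path), named_key_ids=True)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-gene-per-line list (``#`` comments skipped)."""
    path = Path(path)
    genes = [line for _, line in _data_lines(path)]
    return GeneSet.from_iterable(name or path.stem, genes)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gs.members):
            fh.write(g + "\n")


# -- elementary operations -------------------------------------------------


def map_gene_set(net: Network, gs: GeneSet) -> tuple[GeneSet, int]:
    """Intersect a gene set with the network's nodes.

    Returns the mapped :class:`GeneSet` and the count of unmapped members.
    """
    mapped = gs.members & set(net.graph.nodes)
    return GeneSet(name=gs.name, members=frozenset(mapped)), len(gs.members) - len(mapped)


def degree(net: Network, node: object) -> int:
    node = normalize_gene(node)
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network {net.name!r}")
    return net.graph.degree(node)


def shortest_path_lengths(net: Network, source: object) -> dict[str, int]:
    """Breadth-first hop distances from ``source`` to every reachable node.

    Distance to self is 0; unreachable nodes are absent from the map.
    """
    source = normalize_gene(source)
    if source not in net.graph:
        raise KeyError(f"node {source!r} not in network {net.name!r}")
    return dict(nx.single_source_shortest_path_length(net.graph, source))


def clustering_coefficient(net: Network, node: object) -> float:
    """Local clustering coefficient; 0 by convention for degree < 2."""
    node = normalize_gene(node)
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network {net.name!r}")
    return nx.clustering(net.graph, node)


def induced_subgraph(net: Network, keep: Iterable[object], name: str | None = None) -> Network:
    """Subgraph on ``keep`` ∩ nodes with every edge whose endpoints are kept."""
    keep_set = {normalize_gene(k) for k in keep} & set(net.graph.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(keep_set)
    sub.add_edges_from(
        (u, v) for u, v in net.graph.edges(keep_set) if u in keep_set and v in keep_set
    )
    return Network(sub, name=name or f"{net.name}|induced")


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest component.

    Ties are broken by the lexicographically smallest member identifier.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network has no components")
    comps = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), min(c))
    )
    return induced_subgraph(net, comps[0], name=f"{net.name}|lcc")
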
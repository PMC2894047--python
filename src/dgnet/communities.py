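"""k-clique percolation communities and gene-set peripherality.

A k-clique community is the union of all k-cliques reachable from one
another through a chain of k-cliques sharing exactly k-1 nodes (the
clique-percolation definition popularized by CFinder).  Cliques here are
of fixed size k; a larger complete subgraph contributes all of its
k-subsets.  Communities capture the densely interlocked core of a
network; the fraction of a gene set found inside communities measures
how central vs peripheral the set sits, and typically decreases as k
grows.

k-cliques are enumerated from the maximal cliques (every k-clique is a
k-subset of some maximal clique); two k-cliques are joined when they
share a (k-1)-subset, which for distinct k-cliques is exactly a
(k-1)-node overlap.  Enumeration refuses graphs whose k-clique count
exceeds a configurable budget rather than running unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .network import GeneSet, Network, induced_subgraph

__all__ = [
    "CommunitySet",
    "CliqueBudgetError",
    "clique_percolation",
    "membership_fraction",
    "community_core_split",
]


class CliqueBudgetError(RuntimeError):
    """Raised when the k-clique count exceeds the enumeration budget.

    Raise the budget explicitly, increase k, or reduce the network to its
    dense region before retrying.
    """


@dataclass
class CommunitySet:
    k: int
    communities: list[frozenset[str]]
    clique_count: int
    nodes_in_communities: frozenset[str]
    network_nodes: frozenset[str]


def _kcliques(g: nx.Graph, k: int, budget: int) -> set[frozenset[str]]:
    cliques: set[frozenset[str]] = set()
    for maximal in nx.find_cliques(g):
        if len(maximal) < k:
            continue
        for sub in combinations(sorted(maximal), k):
            cliques.add(frozenset(sub))
            if len(cliques) > budget:
                raise CliqueBudgetError(
                    f"more than {budget} {k}-cliques; raise the budget or "
                    "restrict the network to its dense region"
                )
    return cliques


def clique_percolation(net: Network, k: int, budget: int = 10**6) -> CommunitySet:
    """All k-clique percolation communities of a network.

    Two k-cliques are adjacent iff they share exactly k-1 nodes;
    communities are the node unions of connected components of that
    adjacency relation, sorted by decreasing size then by smallest
    member.  Requires k >= 3.
    """
    if k < 3:
        raise ValueError(f"clique percolation requires k >= 3, got {k}")
    cliques = sorted(_kcliques(net.graph, k, budget), key=sorted)

    # union-find over cliques; two cliques sharing a (k-1)-subset overlap
    # in exactly k-1 nodes (distinct k-sets can share at most k-1)
    parent = list(range(len(cliques)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_subset: dict[frozenset[str], int] = {}
    for i, clique in enumerate(cliques):
        for sub in combinations(sorted(clique), k - 1):
            key = frozenset(sub)
            if key in by_subset:
                ri, rj = find(i), find(by_subset[key])
                if ri != rj:
                    parent[ri] = rj
            else:
                by_subset[key] = i

    groups: dict[int, set[str]] = {}
    for i, clique in enumerate(cliques):
        groups.setdefault(find(i), set()).update(clique)
    communities = sorted(
        (frozenset(nodes) for nodes in groups.values()),
        key=lambda c: (-len(c), min(c)),
    )
    members = frozenset().union(*communities) if communities else frozenset()
    return CommunitySet(
        k=k,
        communities=list(communities),
        clique_count=len(cliques),
        nodes_in_communities=members,
        network_nodes=frozenset(net.graph.nodes),
    )


def membership_fraction(cs: CommunitySet, gs: GeneSet) -> float:
    """Fraction of the mapped gene set lying inside any community."""
    mapped = gs.members & cs.network_nodes
    if not mapped:
        raise ValueError(
            f"gene set {gs.name!r} is disjoint from the community set's network"
        )
    return len(mapped & cs.nodes_in_communities) / len(mapped)


def community_core_split(net: Network, cs: CommunitySet) -> tuple[Network, Network]:
    """Split a network into its community core and the remaining periphery.

    Core: induced subgraph on all community members.  Periphery: induced
    subgraph on the complement.  Removing the core typically leaves the
    periphery loosely connected.
    """
    core = induced_subgraph(net, cs.nodes_in_communities, name=f"{net.name}|core")
    periphery = induced_subgraph(
        net, set(net.graph.nodes) - set(cs.nodes_in_communities), name=f"{net.name}|periphery"
    )
    return core, periphery
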
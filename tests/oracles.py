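"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration, deliberately
sharing no code with the implementation it checks.
"""

from itertools import combinations
from math import comb, inf

import networkx as nx


def steiner_optimum_edges(g: nx.Graph, terminals: set) -> int:
    """Minimum Steiner tree edge count by enumeration over vertex subsets.

    The optimum equals min(|S| - 1) over all supersets S of the terminals
    whose induced subgraph is connected (a spanning tree of the smallest
    such S is an optimal Steiner tree).
    """
    nodes = sorted(g.nodes)
    others = [n for n in nodes if n not in terminals]
    best = inf
    for extra in range(len(others) + 1):
        if len(terminals) + extra - 1 >= best:
            break
        for added in combinations(others, extra):
            subset = set(terminals) | set(added)
            if nx.is_connected(g.subgraph(subset)):
                best = min(best, len(subset) - 1)
                break
    return best


def clique_percolation_naive(g: nx.Graph, k: int) -> list[frozenset]:
    """Communities by exhaustive k-subset clique enumeration.

    Every k-subset of nodes is tested for being a clique; two cliques are
    adjacent iff they share exactly k-1 nodes; communities are node
    unions of connected components of the clique adjacency graph,
    sorted canonically (size descending, then smallest member).
    """
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    cliques = []
    for subset in combinations(sorted(g.nodes), k):
        if all(v in adj[u] for u, v in combinations(subset, 2)):
            cliques.append(frozenset(subset))
    cg = nx.Graph()
    cg.add_nodes_from(range(len(cliques)))
    for i, j in combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            cg.add_edge(i, j)
    comms = []
    for comp in nx.connected_components(cg):
        nodes = frozenset().union(*(cliques[i] for i in comp))
        comms.append(nodes)
    return sorted(comms, key=lambda c: (-len(c), min(c)))


def fisher_greater_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher p by direct hypergeometric enumeration.

    With margins fixed, the a-cell ranges over [max(0, r1-c2), min(r1, c1)];
    each table's probability is C(c1, a) C(c2, b) / C(n, r1).
    """
    r1, c1, c2, n = a + b, a + c, b + d, a + b + c + d
    denom = comb(n, r1)
    lo, hi = max(0, r1 - c2), min(r1, c1)
    return sum(comb(c1, x) * comb(c2, r1 - x) for x in range(a, hi + 1)) / denom


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of tables no more probable than the observed."""
    r1, c1, c2, n = a + b, a + c, b + d, a + b + c + d
    denom = comb(n, r1)
    lo, hi = max(0, r1 - c2), min(r1, c1)
    probs = {x: comb(c1, x) * comb(c2, r1 - x) / denom for x in range(lo, hi + 1)}
    observed = probs[a]
    return sum(p for p in probs.values() if p <= observed * (1 + 1e-9))


def wilcoxon_exact_enumeration(a: list, b: list) -> float:
    """Two-sided rank-sum p by enumeration of all label assignments."""
    import numpy as np
    from scipy.stats import rankdata

    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    na = len(a)
    observed = ranks[:na].sum()
    center = na * (len(pooled) + 1) / 2
    count = total = 0
    for pos in combinations(range(len(pooled)), na):
        w = ranks[list(pos)].sum()
        total += 1
        if abs(w - center) >= abs(observed - center) - 1e-9:
            count += 1
    return count / total
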
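"""Pathway enrichment filtering and pairwise pathway-crosstalk statistics.

Enrichment of a disease gene set in each pathway is assessed by a
one-sided Fisher's exact test against a background gene universe; a
pathway passes the filter when its score (-log10 p) exceeds 2 (p < 0.01)
and it contains more than 5 disease genes.

Crosstalk between two pathways asks whether they share more genes
(nodes) or more interactions (links, interactome edges with both
endpoints inside a pathway) than the average pathway pair.  For each
unordered pair a 2x2 table (n, N-n, r, R-r) is built, where n is the
pair's shared-gene (or shared-link) count, N the summed sizes of the two
pathways, and r, R the across-all-pairs averages of n and N (rounded to
integers for the exact test; unrounded values are retained).  Node and
link p-value vectors are each adjusted by Benjamini-Hochberg FDR; a pair
is called significant when the smaller of its two raw p-values falls
below the significance threshold (default 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import GeneSet, Network, normalize_gene

__all__ = [
    "PathwayCollection",
    "EnrichmentResult",
    "CrosstalkResult",
    "read_gmt",
    "write_gmt",
    "fisher_exact_2x2",
    "pathway_enrichment",
    "pathway_link_set",
    "crosstalk_all_pairs",
    "bh_fdr",
    "crosstalk_graph",
]


@dataclass
class PathwayCollection:
    """Named pathway gene sets (identifiers case-normalized, none empty)."""

    pathways: dict[str, frozenset[str]]
    source: str = "unknown"

    def __post_init__(self) -> None:
        cleaned: dict[str, frozenset[str]] = {}
        for name, genes in self.pathways.items():
            members = frozenset(normalize_gene(g) for g in genes)
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
            cleaned[name] = members
        self.pathways = cleaned

    def __len__(self) -> int:
        return len(self.pathways)

    def all_genes(self) -> frozenset[str]:
        return frozenset().union(*self.pathways.values()) if self.pathways else frozenset()

    def subset(self, names: Iterable[str]) -> "PathwayCollection":
        keep = set(names)
        return PathwayCollection(
            {n: g for n, g in self.pathways.items() if n in keep}, source=self.source
        )


def read_gmt(path: str | Path, source: str | None = None) -> PathwayCollection:
    """Read a GMT file (tab-separated: name, description, genes...)."""
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {fields[0]!r} has no genes")
            pathways[fields[0]] = frozenset(normalize_gene(g) for g in genes)
    return PathwayCollection(pathways, source=source or path.stem)


def write_gmt(pc: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pc.pathways):
            genes = "\t".join(sorted(pc.pathways[name]))
            fh.write(f"{name}\t{pc.source}\t{genes}\n")


# -- exact test and FDR ----------------------------------------------------


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: Literal["greater", "two-sided"] = "greater"
) -> float:
    """Fisher's exact test p-value for the 2x2 table [[a, b], [c, d]].

    ``greater`` gives the upper hypergeometric tail of the a-cell;
    ``two-sided`` sums all tables with probability <= the observed one.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    if sum(counts) == 0:
        raise ValueError("empty table: at least one margin must be positive")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (original input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


# -- enrichment ------------------------------------------------------------


@dataclass
class EnrichmentResult:
    pathway: str
    overlap_count: int
    pathway_size: int
    p_value: float
    score: float  # -log10 p
    passes_filter: bool


def pathway_enrichment(
    pc: PathwayCollection,
    disease: GeneSet,
    background: GeneSet,
    score_threshold: float = 2.0,
    min_overlap: int = 5,
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of a disease set in each pathway.

    The disease set is intersected with the background; pathway genes
    outside the background are dropped.  A pathway passes the filter when
    score > ``score_threshold`` and overlap_count > ``min_overlap``.
    Results are sorted by ascending p (ties by name).
    """
    bg = set(background.members)
    disease_bg = disease.members & bg
    if not disease_bg:
        raise ValueError(
            f"disease set {disease.name!r} has no member inside the background"
        )
    results = []
    for name in sorted(pc.pathways):
        pw = pc.pathways[name] & bg
        overlap = len(pw & disease_bg)
        a = overlap
        b = len(pw) - overlap
        c = len(disease_bg) - overlap
        d = len(bg) - len(pw) - c
        p = fisher_exact_2x2(a, b, c, d, alternative="greater")
        score = -math.log10(p) if p > 0 else math.inf
        results.append(
            EnrichmentResult(
                pathway=name,
                overlap_count=overlap,
                pathway_size=len(pw),
                p_value=p,
                score=score,
                passes_filter=(score > score_threshold and overlap > min_overlap),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


# -- crosstalk -------------------------------------------------------------


def pathway_link_set(net: Network, pathway_genes: Iterable[str]) -> set[tuple[str, str]]:
    """Interactome edges with both endpoints inside the pathway gene set."""
    genes = {normalize_gene(g) for g in pathway_genes} & set(net.graph.nodes)
    return {
        tuple(sorted((u, v)))
        for u, v in net.graph.edges(genes)
        if u in genes and v in genes
    }


@dataclass
class CrosstalkResult:
    pathway_a: str
    pathway_b: str
    n_common_nodes: int
    total_nodes: int
    mean_common_nodes: float
    mean_total_nodes: float
    n_common_links: int
    total_links: int
    mean_common_links: float
    mean_total_links: float
    p_nodes: float
    p_links: float
    q_nodes: float
    q_links: float
    p_min: float
    significant: bool


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def crosstalk_all_pairs(
    pc: PathwayCollection,
    net: Network,
    alpha: float = 0.01,
    size_mode: Literal["sum", "union"] = "sum",
) -> list[CrosstalkResult]:
    """Pairwise crosstalk tests over a (filtered) pathway collection.

    For every unordered pathway pair, shared genes and shared interactome
    links are compared against the across-all-pairs averages via a
    one-sided Fisher test on (n, N-n, round(r), round(R-r)).  N sums the
    two pathways' sizes by default (``union`` uses the union size
    instead).  BH-FDR is applied separately to the node and link p-value
    vectors; significance is p_min < alpha on the raw p-values.
    """
    names = sorted(pc.pathways)
    if len(names) < 3:
        raise ValueError(f"crosstalk needs >= 3 pathways, got {len(names)}")
    links = {name: pathway_link_set(net, pc.pathways[name]) for name in names}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]

    node_n, node_N, link_n, link_N = [], [], [], []
    for a, b in pairs:
        ga, gb = pc.pathways[a], pc.pathways[b]
        la, lb = links[a], links[b]
        node_n.append(len(ga & gb))
        link_n.append(len(la & lb))
        if size_mode == "sum":
            node_N.append(len(ga) + len(gb))
            link_N.append(len(la) + len(lb))
        else:
            node_N.append(len(ga | gb))
            link_N.append(len(la | lb))

    r_nodes = float(np.mean(node_n))
    R_nodes = float(np.mean(node_N))
    r_links = float(np.mean(link_n))
    R_links = float(np.mean(link_N))
    ri_n, Ri_n = _round_half_up(r_nodes), _round_half_up(R_nodes)
    ri_l, Ri_l = _round_half_up(r_links), _round_half_up(R_links)

    p_nodes = [
        fisher_exact_2x2(n, N - n, ri_n, max(Ri_n - ri_n, 0), "greater")
        for n, N in zip(node_n, node_N)
    ]
    p_links = []
    for n, N in zip(link_n, link_N):
        if N == 0 and Ri_l == 0:
            p_links.append(1.0)  # no links anywhere: nothing to test
        else:
            p_links.append(fisher_exact_2x2(n, N - n, ri_l, max(Ri_l - ri_l, 0), "greater"))
    q_nodes = bh_fdr(p_nodes)
    q_links = bh_fdr(p_links)

    results = []
    for i, (a, b) in enumerate(pairs):
        p_min = min(p_nodes[i], p_links[i])
        results.append(
            CrosstalkResult(
                pathway_a=a,
                pathway_b=b,
                n_common_nodes=node_n[i],
                total_nodes=node_N[i],
                mean_common_nodes=r_nodes,
                mean_total_nodes=R_nodes,
                n_common_links=link_n[i],
                total_links=link_N[i],
                mean_common_links=r_links,
                mean_total_links=R_links,
                p_nodes=p_nodes[i],
                p_links=p_links[i],
                q_nodes=q_nodes[i],
                q_links=q_links[i],
                p_min=p_min,
                significant=p_min < alpha,
            )
        )
    return results


def crosstalk_graph(
    results: Sequence[CrosstalkResult],
    enrichment_scores: Mapping[str, float] | None = None,
) -> Network:
    """Pathway-level graph: nodes are pathways, edges the significant pairs.

    Node attribute ``score`` carries the enrichment score when provided.
    """
    import networkx as nx

    g = nx.Graph()
    for r in results:
        g.add_node(r.pathway_a)
        g.add_node(r.pathway_b)
        if r.significant:
            g.add_edge(r.pathway_a, r.pathway_b, p_min=r.p_min)
    if enrichment_scores:
        for name, score in enrichment_scores.items():
            if name in g:
                g.nodes[name]["score"] = float(score)
    return Network(g, name="pathway-crosstalk")
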
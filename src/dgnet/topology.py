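"""Per-gene-set topology statistics with resampling-based significance.

For a gene set mapped onto the interactome this module computes, per gene:
degree (number of interaction partners), the characteristic shortest-path
distance (mean hop count from the gene to every other reachable node in
the whole network) and global centrality (mean hop count to the other
mapped members of the same set, paths free to pass through non-members).
Hubs are defined by a degree cutoff, either supplied explicitly or derived
from the degree distribution's upper tail.

Significance of a set-level statistic is assessed by an empirical
resampling test: draw many uniform node sets of the same size, recompute
the statistic, and report the fraction of draws strictly more extreme than
the observation in the stated direction.  Between-set location shifts are
tested with the Wilcoxon rank-sum test.

Shortest-path computation is delegated to ``scipy.sparse.csgraph`` (BFS in
compiled code) so whole-interactome summaries stay cheap; unreachable node
pairs are excluded from averages, with the excluded count reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy import stats

from .network import GeneSet, Network, map_gene_set, normalize_gene

__all__ = [
    "TopologySummary",
    "EmpiricalTestResult",
    "WilcoxonResult",
    "summarize_topology",
    "hub_cutoff_auto",
    "resample_empirical_p",
    "wilcoxon_rank_sum",
    "degree_interval_counts",
]

Direction = Literal["greater", "less"]


@dataclass
class TopologySummary:
    """Topology statistics for one gene set mapped onto a network."""

    set_name: str
    per_gene_degree: dict[str, int]
    average_degree: float
    degree_histogram: dict[int, int]
    characteristic_spd: dict[str, float]
    global_centrality: dict[str, float]
    hub_cutoff: int
    hub_fraction: float
    hub_method: str
    n_unmapped: int
    n_unreachable_pairs_spd: int
    n_unreachable_pairs_centrality: int

    @property
    def average_characteristic_spd(self) -> float:
        vals = [v for v in self.characteristic_spd.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def average_global_centrality(self) -> float:
        vals = [v for v in self.global_centrality.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass(frozen=True)
class EmpiricalTestResult:
    """An observed statistic with its resampling null.

    ``empirical_p`` is the fraction of the ``n_reps`` random draws whose
    statistic was strictly more extreme than ``observed`` in ``direction``.
    """

    statistic_name: str
    observed: float
    n_reps: int
    n_exceeding: int
    empirical_p: float
    direction: Direction
    seed: int
    null_mean: float = float("nan")
    null_sd: float = float("nan")

    def __post_init__(self) -> None:
        assert 0 <= self.n_exceeding <= self.n_reps
        assert abs(self.empirical_p - self.n_exceeding / self.n_reps) < 1e-12


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    method: str  # "exact" or "normal-approximation"


# -- shortest-path machinery ----------------------------------------------


def _csgraph(net: Network) -> tuple[list[str], dict[str, int], sp.csr_matrix]:
    nodes = net.sorted_nodes()
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for u, v in net.graph.edges:
        iu, iv = index[u], index[v]
        rows.extend((iu, iv))
        cols.extend((iv, iu))
    data = np.ones(len(rows), dtype=np.int8)
    mat = sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
    return nodes, index, mat


def _distance_rows(
    mat: sp.csr_matrix, indices: Sequence[int], chunk: int = 512
) -> np.ndarray:
    """Hop-distance rows (inf for unreachable) for the given source indices."""
    out = np.empty((len(indices), mat.shape[0]))
    for start in range(0, len(indices), chunk):
        idx = list(indices[start : start + chunk])
        out[start : start + len(idx)] = dijkstra(
            mat, directed=False, unweighted=True, indices=idx
        )
    return out


def mean_distances_per_node(net: Network, sources: Sequence[str]) -> tuple[dict[str, float], int]:
    """Mean hop distance from each source to all other reachable nodes.

    Returns the per-source means and the total count of (source, node)
    pairs excluded for being unreachable.  Sources with no reachable
    partner get NaN.
    """
    nodes, index, mat = _csgraph(net)
    src_idx = [index[s] for s in sources]
    dist = _distance_rows(mat, src_idx)
    n = mat.shape[0]
    means: dict[str, float] = {}
    excluded = 0
    for row, s in zip(dist, sources):
        finite = row[np.isfinite(row)]
        reachable_others = finite.size - 1  # drop self (distance 0)
        excluded += n - 1 - reachable_others
        means[s] = float(finite.sum() / reachable_others) if reachable_others > 0 else float("nan")
    return means, excluded


# -- hub cutoff ------------------------------------------------------------


def hub_cutoff_auto(net: Network, tail_fraction: float = 0.21) -> int:
    """Smallest degree whose upper-tail node share first drops to <= tail_fraction.

    Operationalizes the "point where the degree distribution straightens
    out": hubs are the nodes in the extreme right tail, by default the top
    ~21% of the distribution.  Requires at least three distinct degrees.
    """
    degrees = np.array([d for _, d in net.graph.degree()])
    distinct = np.unique(degrees)
    if distinct.size < 3:
        raise ValueError(
            "degree distribution too degenerate for an automatic hub cutoff "
            f"({distinct.size} distinct degree values; need >= 3)"
        )
    n = degrees.size
    for d in distinct:
        if (degrees >= d).sum() / n <= tail_fraction:
            return int(d)
    # tail fraction so small even the max degree exceeds it is impossible:
    # the loop always terminates at the maximum degree (share 1/n <= fraction
    # fails only if fraction < 1/n).
    return int(distinct[-1])


# -- per-set summary -------------------------------------------------------


def summarize_topology(
    net: Network,
    gs: GeneSet,
    hub_cutoff: int | Literal["auto"] = "auto",
    tail_fraction: float = 0.21,
) -> TopologySummary:
    """All topology statistics for one gene set on one network.

    ``characteristic_spd`` averages hop distances from each mapped gene to
    every other reachable node of the whole network; ``global_centrality``
    averages distances to the other reachable mapped members only (paths
    may traverse any node).  Raises ValueError when no member maps.
    """
    mapped, n_unmapped = map_gene_set(net, gs)
    if len(mapped) == 0:
        raise ValueError(f"no member of gene set {gs.name!r} maps into the network")
    members = sorted(mapped.members)

    per_gene_degree = {g: net.graph.degree(g) for g in members}
    degs = np.array(list(per_gene_degree.values()))
    average_degree = float(degs.mean())
    histogram: dict[int, int] = {}
    for d in sorted(per_gene_degree.values()):
        histogram[d] = histogram.get(d, 0) + 1

    nodes, index, mat = _csgraph(net)
    src_idx = [index[g] for g in members]
    dist = _distance_rows(mat, src_idx)
    n = mat.shape[0]

    characteristic_spd: dict[str, float] = {}
    excluded_spd = 0
    member_cols = np.array(src_idx)
    global_centrality: dict[str, float] = {}
    excluded_cent = 0
    for row, g in zip(dist, members):
        finite = np.isfinite(row)
        reach = int(finite.sum()) - 1
        excluded_spd += n - 1 - reach
        characteristic_spd[g] = (
            float(row[finite].sum() / reach) if reach > 0 else float("nan")
        )
        mrow = row[member_cols]
        mfin = np.isfinite(mrow)
        mreach = int(mfin.sum()) - 1
        excluded_cent += len(members) - 1 - mreach
        global_centrality[g] = (
            float(mrow[mfin].sum() / mreach) if mreach > 0 else float("nan")
        )

    if hub_cutoff == "auto":
        cutoff = hub_cutoff_auto(net, tail_fraction)
        method = f"auto(tail_fraction={tail_fraction})"
    else:
        cutoff = int(hub_cutoff)
        method = "manual"
    hub_fraction = float((degs >= cutoff).sum() / len(members))

    return TopologySummary(
        set_name=gs.name,
        per_gene_degree=per_gene_degree,
        average_degree=average_degree,
        degree_histogram=histogram,
        characteristic_spd=characteristic_spd,
        global_centrality=global_centrality,
        hub_cutoff=cutoff,
        hub_fraction=hub_fraction,
        hub_method=method,
        n_unmapped=n_unmapped,
        n_unreachable_pairs_spd=excluded_spd,
        n_unreachable_pairs_centrality=excluded_cent,
    )


def degree_interval_counts(
    per_gene_degree: dict[str, int], width: int = 3, start: int = 1
) -> dict[str, int]:
    """Tabulate degrees into half-open intervals [start, start+width), ...

    Output keys are "lo-hi" labels (inclusive upper bound, matching the
    conventional 4-6 / 7-9 presentation for width 3).
    """
    if width < 1:
        raise ValueError("interval width must be >= 1")
    counts: dict[str, int] = {}
    for d in per_gene_degree.values():
        if d < start:
            label = f"<{start}"
        else:
            lo = start + width * ((d - start) // width)
            label = f"{lo}-{lo + width - 1}"
        counts[label] = counts.get(label, 0) + 1
    return counts


# -- resampling ------------------------------------------------------------

_STATISTICS = ("average_degree", "characteristic_spd", "global_centrality", "clustering_coefficient")


def _set_statistic_arrays(net: Network, statistic: str) -> np.ndarray | None:
    """Per-node values whose mean over a sampled set gives the statistic.

    Returns None for global_centrality, which is pairwise and cannot be
    expressed as a per-node value.
    """
    nodes = net.sorted_nodes()
    if statistic == "average_degree":
        return np.array([net.graph.degree(v) for v in nodes], dtype=float)
    if statistic == "clustering_coefficient":
        import networkx as nx

        cc = nx.clustering(net.graph)
        return np.array([cc[v] for v in nodes])
    if statistic == "characteristic_spd":
        means, _ = mean_distances_per_node(net, nodes)
        return np.array([means[v] for v in nodes])
    return None


def resample_empirical_p(
    net: Network,
    statistic: str,
    observed: float,
    set_size: int,
    direction: Direction,
    n_reps: int = 1000,
    seed: int = 0,
) -> EmpiricalTestResult:
    """Empirical p-value for a set-level statistic against uniform node draws.

    Draws ``n_reps`` node sets of ``set_size`` uniformly without
    replacement from the whole network, recomputes the statistic per draw,
    and counts the draws strictly more extreme than ``observed``
    (``greater``: null > observed; ``less``: null < observed).  Ties never
    count as exceeding, so an empirical p of exactly 0 is attainable.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    n = net.n_nodes
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds node count {n}")
    rng = np.random.default_rng(seed)

    per_node = _set_statistic_arrays(net, statistic)
    null_values = np.empty(n_reps)
    if per_node is not None:
        for i in range(n_reps):
            idx = rng.choice(n, size=set_size, replace=False)
            null_values[i] = np.nanmean(per_node[idx])
    else:  # global_centrality: pairwise distances within the sampled set
        nodes, index, mat = _csgraph(net)
        for i in range(n_reps):
            idx = rng.choice(n, size=set_size, replace=False)
            rows = _distance_rows(mat, list(idx))
            sub = rows[:, idx]
            finite = np.isfinite(sub)
            np.fill_diagonal(finite, False)
            per_gene = np.where(
                finite.sum(axis=1) > 0,
                np.nansum(np.where(finite, sub, 0.0), axis=1)
                / np.maximum(finite.sum(axis=1), 1),
                np.nan,
            )
            null_values[i] = np.nanmean(per_gene)

    if direction == "greater":
        n_exceeding = int((null_values > observed).sum())
    else:
        n_exceeding = int((null_values < observed).sum())
    return EmpiricalTestResult(
        statistic_name=statistic,
        observed=float(observed),
        n_reps=n_reps,
        n_exceeding=n_exceeding,
        empirical_p=n_exceeding / n_reps,
        direction=direction,
        seed=seed,
        null_mean=float(np.nanmean(null_values)),
        null_sd=float(np.nanstd(null_values)),
    )


# -- rank test -------------------------------------------------------------


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when the combined sample size is <= 20 and no
    ties are present; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return WilcoxonResult(p_value=float(res.pvalue), method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return WilcoxonResult(p_value=float(min(res.pvalue, 1.0)), method="normal-approximation")
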
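"""Synthetic interactomes, gene sets, pathway collections and GWAS tables.

The generator produces data with the statistical structure the analysis
assumes, so every pipeline stage is testable without downloads:

* **Interactome** — a growth model: start from a complete graph on ``m``
  nodes, attach each new node to ``m`` distinct existing nodes with
  probability proportional to current degree (preferential attachment,
  giving the heavy right-skewed degree distribution of real
  interactomes), and after each attachment close a triangle among the
  new node's neighbors with a tunable probability (giving the clustering
  real interactomes show and community detection needs).  Connected by
  construction.
* **Gene sets** — node samples weighted by degree^exponent: exponent 0
  is uniform, positive exponents emulate hub-rich sets (cancer-like,
  essential-like), negative exponents periphery-dwelling sets.  Optional
  clique planting grows part of the set inside 2-hop neighborhoods of
  already chosen members so the set clusters.
* **Pathways** — connected breadth-first balls around random centers
  (guaranteeing internal links); requested pairwise overlaps are forced
  by sharing a block of members between the two pathways.  A pathway may
  additionally draw a fraction of its members from a named gene set so
  enrichment is planted.
* **GWAS tables** — null genes get p ~ Uniform(0, 1]; signal genes get
  p ~ Beta(a, 1), stochastically small for a < 1 (P(p < t) = t^a).
  Optionally p-values can be made length-biased for bias studies.

Everything is a pure function of the configuration including its master
seed.  Sub-seeds are derived from the master seed through fixed
``numpy.random.SeedSequence`` spawn keys (one fixed stream id per
artifact), so adding a generator call never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import networkx as nx
import numpy as np

from .network import GeneSet, Network
from .pathways import PathwayCollection

if TYPE_CHECKING:  # pragma: no cover
    from .gwas import GwasTable

__all__ = [
    "SetSpec",
    "PathwaySpec",
    "GwasSpec",
    "SyntheticConfig",
    "SyntheticData",
    "generate_interactome",
    "plant_gene_set",
    "generate_pathways",
    "generate_gwas",
    "generate_all",
    "default_config",
]

# fixed stream ids for sub-seed derivation (documented scheme)
_STREAM_INTERACTOME = 0
_STREAM_GENESET_BASE = 100
_STREAM_PATHWAYS = 200
_STREAM_GWAS_BASE = 300


def derive_seed(master_seed: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(stream,))


@dataclass(frozen=True)
class SetSpec:
    name: str
    size: int
    degree_bias_exponent: float = 0.0
    clique_planting: bool = False


@dataclass(frozen=True)
class PathwaySpec:
    count: int = 12
    size_range: tuple[int, int] = (30, 60)
    # (earlier pathway index, later pathway index, target Jaccard)
    overlap_pairs: tuple[tuple[int, int, float], ...] = ()
    # fraction of each of the first `seeded_count` pathways drawn from `seed_set`
    seed_set: str | None = None
    seed_fraction: float = 0.0
    seeded_count: int = 0


@dataclass(frozen=True)
class GwasSpec:
    study_names: tuple[str, ...] = ("STUDY-A", "STUDY-B")
    signal_set: str = "disease-like"
    beta_shape: float = 0.1
    signal_fraction: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_nodes: int = 10_000
    attachment_edges: int = 3
    triangle_closure_prob: float = 0.25
    set_specs: tuple[SetSpec, ...] = ()
    pathway_spec: PathwaySpec = PathwaySpec()
    gwas_spec: GwasSpec = GwasSpec()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if not (1 <= self.attachment_edges < self.n_nodes):
            raise ValueError("attachment_edges must be in [1, n_nodes)")
        if not (0 <= self.triangle_closure_prob <= 1):
            raise ValueError("triangle_closure_prob must lie in [0, 1]")
        for spec in self.set_specs:
            if spec.size > self.n_nodes:
                raise ValueError(f"gene set {spec.name!r} larger than the network")


def config_from_dict(raw: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a plain (JSON-loaded) dictionary."""
    raw = dict(raw)
    set_specs = tuple(SetSpec(**s) for s in raw.pop("set_specs", []))
    pw = raw.pop("pathway_spec", None)
    pathway_spec = PathwaySpec()
    if pw:
        pw = dict(pw)
        pw["overlap_pairs"] = tuple(tuple(t) for t in pw.get("overlap_pairs", ()))
        pw["size_range"] = tuple(pw.get("size_range", (30, 60)))
        pathway_spec = PathwaySpec(**pw)
    gw = raw.pop("gwas_spec", None)
    gwas_spec = GwasSpec()
    if gw:
        gw = dict(gw)
        gw["study_names"] = tuple(gw.get("study_names", ("STUDY-A", "STUDY-B")))
        gwas_spec = GwasSpec(**gw)
    return SyntheticConfig(
        set_specs=set_specs, pathway_spec=pathway_spec, gwas_spec=gwas_spec, **raw
    )


def default_config(master_seed: int = 0) -> SyntheticConfig:
    """The shipped "interactome-like" study configuration.

    Five gene sets mirror the classic disease-genetics contrasts: a
    hub-rich clustered set (cancer-like), a hub-biased set
    (essential-like), a moderately connected disease set, a mildly
    connected set (neuro-like) and a periphery-dwelling neutral set
    (nde-like).  Six of twelve pathways are enriched in the disease set;
    three pathway pairs carry planted overlaps, the rest are random
    balls.
    """
    return SyntheticConfig(
        n_nodes=10_000,
        attachment_edges=3,
        triangle_closure_prob=0.25,
        set_specs=(
            SetSpec("cancer-like", 300, 2.0, True),
            SetSpec("essential-like", 1000, 1.5, False),
            SetSpec("disease-like", 160, 0.7, False),
            SetSpec("neuro-like", 300, 0.3, False),
            SetSpec("nde-like", 500, -0.5, False),
        ),
        pathway_spec=PathwaySpec(
            count=12,
            size_range=(30, 60),
            overlap_pairs=((0, 1, 0.4), (2, 3, 0.35), (4, 5, 0.3)),
            seed_set="disease-like",
            seed_fraction=0.25,
            seeded_count=6,
        ),
        gwas_spec=GwasSpec(
            study_names=("STUDY-A", "STUDY-B"),
            signal_set="disease-like",
            beta_shape=0.1,
        ),
        master_seed=master_seed,
    )


def _node_label(i: int, n: int) -> str:
    width = max(5, len(str(n - 1)))
    return f"G{i:0{width}d}"


def generate_interactome(cfg: SyntheticConfig) -> Network:
    """Preferential-attachment interactome with tunable triangle closure.

    Seed: complete graph on ``attachment_edges`` nodes.  Each new node
    attaches to ``attachment_edges`` distinct existing nodes drawn with
    probability proportional to degree; after each attachment, with
    probability ``triangle_closure_prob``, one edge is added between two
    random neighbors of the new node (if such a non-edge exists).
    """
    n, m = cfg.n_nodes, cfg.attachment_edges
    rng = np.random.default_rng(derive_seed(cfg.master_seed, _STREAM_INTERACTOME))
    labels = [_node_label(i, n) for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(labels[:m])
    for i in range(m):
        for j in range(i + 1, m):
            g.add_edge(labels[i], labels[j])
    degrees = np.zeros(n)
    for i in range(m):
        degrees[i] = m - 1
    for new in range(m, n):
        weights = degrees[:new].copy()
        total = weights.sum()
        if total == 0:
            probs = np.full(new, 1.0 / new)
        else:
            probs = weights / total
        k = min(m, new)
        targets = rng.choice(new, size=k, replace=False, p=probs)
        for t in targets:
            g.add_edge(labels[new], labels[int(t)])
            degrees[new] += 1
            degrees[int(t)] += 1
            if rng.random() < cfg.triangle_closure_prob:
                nbrs = sorted(g.neighbors(labels[new]))
                if len(nbrs) >= 2:
                    a, b = rng.choice(len(nbrs), size=2, replace=False)
                    u, v = nbrs[int(a)], nbrs[int(b)]
                    if not g.has_edge(u, v):
                        g.add_edge(u, v)
                        degrees[int(u[1:])] += 1
                        degrees[int(v[1:])] += 1
    net = Network(g, name="synthetic-interactome")
    return net


def plant_gene_set(
    net: Network,
    name: str,
    size: int,
    degree_bias_exponent: float = 0.0,
    clique_planting: bool = False,
    seed: int | np.random.SeedSequence = 0,
) -> GeneSet:
    """Sample a gene set with degree-biased (and optionally clustered) members.

    Sampling weight is degree^exponent (isolated nodes weighted as
    degree 1); with ``clique_planting`` half the set is drawn that way
    and the rest grown inside 2-hop neighborhoods of already chosen
    members, biasing the set toward triangles.
    """
    nodes = net.sorted_nodes()
    if size > len(nodes):
        raise ValueError(f"requested size {size} exceeds network size {len(nodes)}")
    if size == len(nodes):
        return GeneSet.from_iterable(name, nodes)
    rng = np.random.default_rng(seed)
    deg = np.array([max(net.graph.degree(v), 1) for v in nodes], dtype=float)
    weights = deg**degree_bias_exponent
    probs = weights / weights.sum()

    if not clique_planting:
        idx = rng.choice(len(nodes), size=size, replace=False, p=probs)
        return GeneSet.from_iterable(name, (nodes[int(i)] for i in idx))

    index = {v: i for i, v in enumerate(nodes)}
    n_core = max(size // 2, 1)
    core_idx = rng.choice(len(nodes), size=n_core, replace=False, p=probs)
    chosen = {nodes[int(i)] for i in core_idx}
    while len(chosen) < size:
        anchor = sorted(chosen)[int(rng.integers(len(chosen)))]
        hood = set(net.graph.neighbors(anchor))
        for nb in list(hood):
            hood.update(net.graph.neighbors(nb))
        hood -= chosen
        if not hood:
            # neighborhood exhausted: fall back to a global biased draw
            extra = rng.choice(len(nodes), size=1, p=probs)
            chosen.add(nodes[int(extra[0])])
            continue
        cand = sorted(hood)
        w = np.array([weights[index[c]] for c in cand])
        pick = rng.choice(len(cand), p=w / w.sum())
        chosen.add(cand[int(pick)])
    return GeneSet.from_iterable(name, chosen)


def _bfs_ball(g: nx.Graph, center: str, size: int, exclude: set[str], rng: np.random.Generator) -> list[str]:
    """Connected node sample of ~size grown breadth-first from center."""
    ball = [center]
    seen = {center} | exclude
    frontier = [center]
    while len(ball) < size and frontier:
        nxt: list[str] = []
        for node in frontier:
            for nb in sorted(g.neighbors(node)):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        rng.shuffle(nxt)
        for nb in nxt:
            if len(ball) >= size:
                break
            ball.append(nb)
        frontier = nxt
    return ball


def generate_pathways(
    net: Network,
    spec: PathwaySpec,
    seed: int | np.random.SeedSequence = 0,
    gene_sets: dict[str, GeneSet] | None = None,
) -> PathwayCollection:
    """Overlap-controlled pathway collection sampled from the network.

    Pathways are breadth-first balls (internally linked).  For each
    (i, j, J) overlap constraint pathway j shares
    round(J * (s_i + s_j) / (1 + J)) members with pathway i.  With a
    ``seed_set``, the first ``seeded_count`` pathways replace
    ``seed_fraction`` of their members with draws from that gene set.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.size_range
    if lo < 3 or hi < lo or hi > net.n_nodes:
        raise ValueError(f"infeasible pathway size range {spec.size_range}")
    overlap_for: dict[int, tuple[int, float]] = {}
    for i, j, jac in spec.overlap_pairs:
        if not (0 <= jac <= 1):
            raise ValueError(f"Jaccard target must lie in [0, 1], got {jac}")
        if not (0 <= i < j < spec.count):
            raise ValueError(f"overlap pair ({i}, {j}) out of range / disordered")
        overlap_for[j] = (i, jac)

    nodes = net.sorted_nodes()
    pathways: dict[str, frozenset[str]] = {}
    members_by_index: list[set[str]] = []
    used: set[str] = set()  # members of earlier pathways; only deliberate
    # shared blocks may recur, so unplanted pairs stay disjoint
    for p in range(spec.count):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        if p in overlap_for:
            src_idx, jac = overlap_for[p]
            src = sorted(members_by_index[src_idx])
            n_shared = round(jac * (len(src) + size) / (1 + jac))
            if n_shared > min(len(src), size):
                raise ValueError(
                    f"infeasible overlap {jac} between pathways {src_idx} and {p}"
                )
            shared = rng.choice(len(src), size=n_shared, replace=False)
            members.update(src[int(i)] for i in shared)
        if (
            spec.seed_set
            and gene_sets
            and p < spec.seeded_count
            and spec.seed_fraction > 0
        ):
            pool = sorted(gene_sets[spec.seed_set].members - members - used)
            n_seeded = min(round(spec.seed_fraction * size), len(pool))
            picks = rng.choice(len(pool), size=n_seeded, replace=False)
            members.update(pool[int(i)] for i in picks)
        exclude = used - members
        while len(members) < size:
            center = nodes[int(rng.integers(len(nodes)))]
            if center in members or center in exclude:
                continue
            grown = _bfs_ball(
                net.graph, center, size - len(members), members | exclude, rng
            )
            members.update(grown)
        pathways[f"PATHWAY-{p:02d}"] = frozenset(members)
        members_by_index.append(members)
        used |= members
    return PathwayCollection(pathways, source="synthetic")


def generate_gwas(
    genes: Sequence[str],
    signal: GeneSet,
    beta_shape: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    study_name: str = "STUDY",
    signal_fraction: float = 1.0,
) -> "GwasTable":
    """One study's gene-level p-values: Uniform null, Beta(a, 1) signal.

    P(p < t) = t^a for signal genes, so a < 1 concentrates signal
    p-values near zero; a = 1 makes signal indistinguishable from null.
    ``signal_fraction`` < 1 leaves part of the signal set null.
    """
    from .gwas import GwasTable

    if not (0 < beta_shape <= 1):
        raise ValueError("beta_shape must lie in (0, 1]")
    genes_sorted = sorted(set(genes))
    missing = signal.members - set(genes_sorted)
    if missing:
        raise ValueError(
            f"signal set {signal.name!r} has {len(missing)} genes outside the universe"
        )
    rng = np.random.default_rng(seed)
    signal_sorted = sorted(signal.members)
    if signal_fraction < 1.0:
        n_active = round(signal_fraction * len(signal_sorted))
        idx = rng.choice(len(signal_sorted), size=n_active, replace=False)
        active = {signal_sorted[int(i)] for i in idx}
    else:
        active = set(signal_sorted)
    p_by_gene: dict[str, float] = {}
    for g in genes_sorted:
        if g in active:
            p = float(rng.beta(beta_shape, 1.0))
        else:
            p = 1.0 - float(rng.random())  # Uniform(0, 1]
        p_by_gene[g] = max(p, 1e-300)
    return GwasTable(study_name=study_name, p_by_gene=p_by_gene)


@dataclass
class SyntheticData:
    config: SyntheticConfig
    network: Network
    gene_sets: dict[str, GeneSet]
    pathways: PathwayCollection
    gwas: list


def generate_all(cfg: SyntheticConfig, signal_set: GeneSet | None = None) -> SyntheticData:
    """Generate the full fixture bundle from one configuration.

    ``signal_set`` overrides the GWAS signal set (e.g. an extracted
    subnetwork's node set); by default the gene set named in
    ``cfg.gwas_spec.signal_set`` carries the signal.
    """
    net = generate_interactome(cfg)
    gene_sets: dict[str, GeneSet] = {}
    for i, spec in enumerate(cfg.set_specs):
        gene_sets[spec.name] = plant_gene_set(
            net,
            spec.name,
            spec.size,
            spec.degree_bias_exponent,
            spec.clique_planting,
            seed=derive_seed(cfg.master_seed, _STREAM_GENESET_BASE + i),
        )
    pathways = generate_pathways(
        net,
        cfg.pathway_spec,
        seed=derive_seed(cfg.master_seed, _STREAM_PATHWAYS),
        gene_sets=gene_sets,
    )
    if signal_set is None:
        signal_set = gene_sets[cfg.gwas_spec.signal_set]
    gwas = [
        generate_gwas(
            net.sorted_nodes(),
            signal_set,
            beta_shape=cfg.gwas_spec.beta_shape,
            seed=derive_seed(cfg.master_seed, _STREAM_GWAS_BASE + j),
            study_name=name,
            signal_fraction=cfg.gwas_spec.signal_fraction,
        )
        for j, name in enumerate(cfg.gwas_spec.study_names)
    ]
    return SyntheticData(
        config=cfg, network=net, gene_sets=gene_sets, pathways=pathways, gwas=gwas
    )
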
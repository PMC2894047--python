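"""GWAS-signal-based candidate gene prioritization.

Two independent gene-level association studies (one smallest p-value per
gene) are intersected with a disease subnetwork: genes significant in
both studies ("joint-significant") that are not already disease seeds
become novel candidates, each accompanied by an ego subnetwork of its
seed / joint-significant neighbors.  Whether the subnetwork carries more
joint signal than chance is tested by randomization: many same-size gene
sets are drawn uniformly from the universe of genes present in both
studies and their joint-significant counts compared to the observation.

Caveat: gene-level smallest p-values are biased toward long genes (more
markers, more chances of a small minimum); no correction is applied
here, matching common practice for this statistic, but the synthetic
generator can induce length-correlated p-values so the bias is
measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import GeneSet, Network, induced_subgraph, normalize_gene
from .steiner import steiner_subnetwork

__all__ = [
    "GwasTable",
    "PrioritizationResult",
    "read_gwas_table",
    "joint_significant_genes",
    "enrichment_randomization",
    "nominate_candidates",
    "pathway_guided_candidates",
]


@dataclass
class GwasTable:
    """One study's smallest association p-value per gene, p in (0, 1]."""

    study_name: str
    p_by_gene: dict[str, float]

    def __post_init__(self) -> None:
        cleaned: dict[str, float] = {}
        for gene, p in self.p_by_gene.items():
            p = float(p)
            if not (0 < p <= 1):
                raise ValueError(
                    f"{self.study_name}: p-value for {gene!r} outside (0, 1]: {p}"
                )
            cleaned[normalize_gene(gene)] = p
        self.p_by_gene = cleaned

    def __len__(self) -> int:
        return len(self.p_by_gene)


def read_gwas_table(path: str | Path, study_name: str | None = None) -> GwasTable:
    """Read a two-column TSV (gene, p); a non-numeric first row is a header."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    genes = df.iloc[:, 0].astype(str)
    pvals = df.iloc[:, 1].astype(float)
    return GwasTable(
        study_name=study_name or path.stem,
        p_by_gene=dict(zip(genes, pvals)),
    )


def joint_significant_genes(
    genes: Iterable[str],
    study_a: GwasTable,
    study_b: GwasTable,
    alpha: float = 0.05,
) -> frozenset[str]:
    """Genes present in both studies with p < alpha in both."""
    out = set()
    for g in genes:
        g = normalize_gene(g)
        pa = study_a.p_by_gene.get(g)
        pb = study_b.p_by_gene.get(g)
        if pa is not None and pb is not None and pa < alpha and pb < alpha:
            out.add(g)
    return frozenset(out)


def enrichment_randomization(
    universe: Iterable[str],
    set_size: int,
    observed_count: int,
    study_a: GwasTable,
    study_b: GwasTable,
    alpha: float = 0.05,
    n_sets: int = 1000,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[float]:
    """Randomization test for joint-signal enrichment of a gene set.

    Per repeat: draw ``n_sets`` uniform subsets of ``set_size`` genes
    from the universe (genes present in both studies), count each
    subset's joint-significant genes, and report the fraction of subsets
    whose count is >= ``observed_count``.  Repeats use seeds derived from
    ``seed`` so the list is reproducible bit-for-bit.
    """
    universe_sorted = sorted({normalize_gene(g) for g in universe})
    universe_sorted = [
        g for g in universe_sorted if g in study_a.p_by_gene and g in study_b.p_by_gene
    ]
    n = len(universe_sorted)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds usable universe size {n}")
    joint = np.array(
        [
            study_a.p_by_gene[g] < alpha and study_b.p_by_gene[g] < alpha
            for g in universe_sorted
        ],
        dtype=bool,
    )
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    empirical_ps = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        m = 0
        for _ in range(n_sets):
            idx = rng.choice(n, size=set_size, replace=False)
            if int(joint[idx].sum()) >= observed_count:
                m += 1
        empirical_ps.append(m / n_sets)
    return empirical_ps


def null_joint_counts(
    universe: Iterable[str],
    set_size: int,
    study_a: GwasTable,
    study_b: GwasTable,
    alpha: float = 0.05,
    n_sets: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Joint-significant counts of n_sets uniform subsets (diagnostics)."""
    universe_sorted = sorted({normalize_gene(g) for g in universe})
    universe_sorted = [
        g for g in universe_sorted if g in study_a.p_by_gene and g in study_b.p_by_gene
    ]
    n = len(universe_sorted)
    joint = np.array(
        [
            study_a.p_by_gene[g] < alpha and study_b.p_by_gene[g] < alpha
            for g in universe_sorted
        ],
        dtype=bool,
    )
    rng = np.random.default_rng(seed)
    counts = np.empty(n_sets, dtype=int)
    for i in range(n_sets):
        idx = rng.choice(n, size=set_size, replace=False)
        counts[i] = int(joint[idx].sum())
    return counts


@dataclass
class PrioritizationResult:
    joint_significant: frozenset[str]
    novel_candidates: frozenset[str]
    empirical_p_per_repeat: list[float]
    n_repeats: int
    ego_subnetworks: dict[str, Network] = field(default_factory=dict)
    caveat: str = (
        "gene-level smallest p-values are biased toward long genes; no "
        "length correction applied"
    )

    def __post_init__(self) -> None:
        assert self.novel_candidates <= self.joint_significant


def nominate_candidates(
    subnet: Network,
    seeds: GeneSet,
    joint: Iterable[str],
    empirical_p_per_repeat: Sequence[float] = (),
) -> PrioritizationResult:
    """Novel candidates: joint-significant subnetwork genes outside the seeds.

    Each candidate's ego subnetwork is the induced subgraph on the
    candidate plus its subnetwork neighbors that are seeds or
    joint-significant (the candidate's direct evidence context).
    """
    joint_set = frozenset(normalize_gene(g) for g in joint)
    joint_in_subnet = joint_set & set(subnet.graph.nodes)
    candidates = frozenset(joint_in_subnet - seeds.members)
    egos: dict[str, Network] = {}
    for cand in sorted(candidates):
        keep = {cand} | {
            nb
            for nb in subnet.graph.neighbors(cand)
            if nb in seeds.members or nb in joint_set
        }
        egos[cand] = induced_subgraph(subnet, keep, name=f"ego-{cand}")
    return PrioritizationResult(
        joint_significant=joint_in_subnet,
        novel_candidates=candidates,
        empirical_p_per_repeat=list(empirical_p_per_repeat),
        n_repeats=len(empirical_p_per_repeat),
        ego_subnetworks=egos,
    )


def pathway_guided_candidates(
    net: Network,
    pathway_genes: Iterable[str],
    seeds: GeneSet,
) -> list[str]:
    """Non-seed genes of a pathway's Steiner subnetwork, most central first.

    Extracts the Steiner subnetwork spanning the pathway genes and
    returns its non-seed nodes ranked by degree within the subnetwork
    (descending; ties broken lexicographically) — the high-degree
    connectors are the strongest positional candidates.
    """
    terminals = GeneSet.from_iterable("pathway-terminals", pathway_genes)
    result = steiner_subnetwork(net, terminals, include_induced_edges=True)
    sub = result.subnetwork
    non_seed = [g for g in sub.graph.nodes if g not in seeds.members]
    return sorted(non_seed, key=lambda g: (-sub.graph.degree(g), g))
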
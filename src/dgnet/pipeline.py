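"""End-to-end pipeline: topology → subnetwork → communities → pathways →
GWAS prioritization, from one configuration, with a machine-readable report.

The pipeline runs the full disease-gene workflow in dependency order on
either user-supplied inputs (network, gene-set files, GMT, two GWAS
tables) or a synthetic configuration.  Every stage writes its tabular
artifacts (TSV) and networks (GraphML + edge list) under the output
directory and contributes a block to a single JSON report carrying every
statistic, empirical p-value, seed and parameter.  A rerun with the same
configuration is byte-identical.

Stage errors abort the run naming the failing stage; artifacts of
completed stages are retained together with a MANIFEST listing them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import communities as comm
from . import gwas as gwasmod
from . import pathways as pathmod
from . import simulate
from . import steiner as steinermod
from . import topology as topo
from .network import (
    GeneSet,
    Network,
    map_gene_set,
    read_gene_set,
    read_network,
    write_edge_list,
    write_graphml,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1

# pipeline-stage seed streams (continuing the scheme in `simulate`)
_STREAM_TOPOLOGY = 400
_STREAM_NONRANDOM = 410
_STREAM_GWAS_RANDOMIZATION = 420


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of synthetic / real inputs."""

    outdir: str = "dgnet-run"
    master_seed: int = 0
    synthetic: simulate.SyntheticConfig | None = None
    network_path: str | None = None
    gene_set_paths: tuple[str, ...] = ()
    disease_set: str = "disease-like"
    gmt_path: str | None = None
    gwas_paths: tuple[str, str] | None = None
    # stage parameters
    n_resample_reps: int = 1000
    hub_tail_fraction: float = 0.21
    nonrandomness_reps: int = 1000
    k_values: tuple[int, ...] = (3, 4, 5, 6, 7)
    clique_budget: int = 10**6
    enrichment_score_threshold: float = 2.0
    enrichment_min_overlap: int = 5
    crosstalk_alpha: float = 0.01
    gwas_alpha: float = 0.05
    n_random_sets: int = 1000
    n_repeats: int = 10
    include_induced_edges: bool = True

    def __post_init__(self) -> None:
        has_synth = self.synthetic is not None
        has_real = self.network_path is not None
        if has_synth == has_real:
            raise ValueError(
                "exactly one of a synthetic config or a real network path "
                "must be supplied"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw.get("synthetic"), dict):
            raw["synthetic"] = simulate.config_from_dict(raw["synthetic"])
        for key in ("gene_set_paths", "k_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("gwas_paths"):
            raw["gwas_paths"] = tuple(raw["gwas_paths"])
        return cls(**raw)


def _derived_int_seed(master_seed: int, stream: int, index: int = 0) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _write_tsv(path: Path, header: list[str], rows: list[list[Any]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# -- stages ----------------------------------------------------------------


def _stage_data(cfg: RunConfig, out: Path) -> dict[str, Any]:
    if cfg.synthetic is not None:
        net = simulate.generate_interactome(cfg.synthetic)
        gene_sets: dict[str, GeneSet] = {}
        for i, spec in enumerate(cfg.synthetic.set_specs):
            gene_sets[spec.name] = simulate.plant_gene_set(
                net,
                spec.name,
                spec.size,
                spec.degree_bias_exponent,
                spec.clique_planting,
                seed=simulate.derive_seed(
                    cfg.synthetic.master_seed, simulate._STREAM_GENESET_BASE + i
                ),
            )
        pc = (
            simulate.generate_pathways(
                net,
                cfg.synthetic.pathway_spec,
                seed=simulate.derive_seed(
                    cfg.synthetic.master_seed, simulate._STREAM_PATHWAYS
                ),
                gene_sets=gene_sets,
            )
            if cfg.synthetic.pathway_spec.count > 0
            else None
        )
        source = "synthetic"
    else:
        net = read_network(cfg.network_path)
        gene_sets = {}
        for p in cfg.gene_set_paths:
            gs = read_gene_set(p)
            gene_sets[gs.name] = gs
        pc = pathmod.read_gmt(cfg.gmt_path) if cfg.gmt_path else None
        source = "files"
    if cfg.disease_set not in gene_sets:
        raise ValueError(f"disease set {cfg.disease_set!r} not among gene sets")
    block = {
        "source": source,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "gene_sets": {name: len(gs) for name, gs in sorted(gene_sets.items())},
        "n_pathways": len(pc) if pc else 0,
    }
    return {"network": net, "gene_sets": gene_sets, "pathways": pc, "block": block}


def _stage_topology(cfg: RunConfig, net: Network, gene_sets: dict[str, GeneSet], out: Path) -> dict:
    block: dict[str, Any] = {"sets": {}, "n_reps": cfg.n_resample_reps}
    summaries: dict[str, topo.TopologySummary] = {}
    cutoff = topo.hub_cutoff_auto(net, cfg.hub_tail_fraction)
    rows = []
    for i, name in enumerate(sorted(gene_sets)):
        summary = topo.summarize_topology(net, gene_sets[name], hub_cutoff=cutoff)
        summaries[name] = summary
        seed = _derived_int_seed(cfg.master_seed, _STREAM_TOPOLOGY, i)
        res = topo.resample_empirical_p(
            net,
            "average_degree",
            summary.average_degree,
            set_size=len(summary.per_gene_degree),
            direction="greater",
            n_reps=cfg.n_resample_reps,
            seed=seed,
        )
        block["sets"][name] = {
            "n_mapped": len(summary.per_gene_degree),
            "n_unmapped": summary.n_unmapped,
            "average_degree": summary.average_degree,
            "average_characteristic_spd": summary.average_characteristic_spd,
            "average_global_centrality": summary.average_global_centrality,
            "hub_cutoff": summary.hub_cutoff,
            "hub_fraction": summary.hub_fraction,
            "degree_empirical_p": res.empirical_p,
            "degree_null_mean": res.null_mean,
            "resample_seed": seed,
        }
        rows.append(
            [
                name,
                len(summary.per_gene_degree),
                f"{summary.average_degree:.4f}",
                f"{res.empirical_p:.4f}",
                f"{summary.average_characteristic_spd:.4f}",
                f"{summary.average_global_centrality:.4f}",
                f"{summary.hub_fraction:.4f}",
                cfg.n_resample_reps,
                seed,
            ]
        )
    _write_tsv(
        out / "topology_summary.tsv",
        [
            "set",
            "n_mapped",
            "average_degree",
            "degree_empirical_p",
            "avg_characteristic_spd",
            "avg_global_centrality",
            "hub_fraction",
            "n_reps",
            "seed",
        ],
        rows,
    )
    # pairwise degree comparisons against the disease set
    disease = cfg.disease_set
    block["wilcoxon_vs_disease"] = {}
    ddeg = list(summaries[disease].per_gene_degree.values())
    for name in sorted(gene_sets):
        if name == disease:
            continue
        w = topo.wilcoxon_rank_sum(ddeg, list(summaries[name].per_gene_degree.values()))
        block["wilcoxon_vs_disease"][name] = {"p_value": w.p_value, "method": w.method}
    block["hub_cutoff"] = cutoff
    return {"block": block, "summaries": summaries}


def _stage_subnet(cfg: RunConfig, net: Network, disease: GeneSet, out: Path) -> dict:
    result = steinermod.steiner_subnetwork(
        net, disease, include_induced_edges=cfg.include_induced_edges
    )
    sub = result.subnetwork
    seed = _derived_int_seed(cfg.master_seed, _STREAM_NONRANDOM)
    null_report = steinermod.nonrandomness_test(
        sub, n_reps=cfg.nonrandomness_reps, seed=seed
    )
    write_edge_list(sub, out / "subnetwork.edges.tsv")
    write_graphml(
        sub,
        out / "subnetwork.graphml",
        node_attrs={
            "is_terminal": {n: (n in result.terminals_included) for n in sub.graph.nodes},
            "degree_in_interactome": {n: net.graph.degree(n) for n in sub.graph.nodes},
        },
    )
    _write_tsv(
        out / "subnetwork_nullmodel.tsv",
        ["metric", "observed", "null_mean", "null_sd", "n_greater", "n_less", "empirical_p", "direction"],
        [
            [m, f"{v.observed:.4f}", f"{v.null_mean:.4f}", f"{v.null_sd:.4f}", v.n_greater, v.n_less, f"{v.empirical_p:.4f}", v.direction]
            for m, v in sorted(null_report.metrics.items())
        ],
    )
    block = {
        "n_nodes": sub.n_nodes,
        "n_edges": sub.n_edges,
        "n_terminals_included": len(result.terminals_included),
        "n_terminals_unreachable": len(result.terminals_unreachable),
        "n_steiner_nodes": len(result.steiner_nodes),
        "tree_edge_count": result.tree_edge_count,
        "algorithm": result.algorithm,
        "include_induced_edges": cfg.include_induced_edges,
        "nonrandomness": {
            m: asdict(v) for m, v in sorted(null_report.metrics.items())
        },
        "nonrandomness_reps": cfg.nonrandomness_reps,
        "nonrandomness_seed": seed,
    }
    return {"block": block, "result": result}


def _stage_communities(
    cfg: RunConfig, sub: Network, gene_sets: dict[str, GeneSet], out: Path
) -> dict:
    block: dict[str, Any] = {"by_k": {}}
    rows = []
    for k in cfg.k_values:
        cs = comm.clique_percolation(sub, k, budget=cfg.clique_budget)
        entry: dict[str, Any] = {
            "clique_count": cs.clique_count,
            "n_communities": len(cs.communities),
            "n_nodes_in_communities": len(cs.nodes_in_communities),
            "membership_fraction": {},
        }
        for name in sorted(gene_sets):
            mapped = gene_sets[name].members & cs.network_nodes
            frac = comm.membership_fraction(cs, gene_sets[name]) if mapped else None
            entry["membership_fraction"][name] = frac
            rows.append(
                [k, name, cs.clique_count, len(cs.communities), "" if frac is None else f"{frac:.4f}"]
            )
        block["by_k"][str(k)] = entry
    _write_tsv(
        out / "communities.tsv",
        ["k", "set", "clique_count", "n_communities", "membership_fraction"],
        rows,
    )
    return {"block": block}


def _stage_pathways(
    cfg: RunConfig,
    net: Network,
    pc: pathmod.PathwayCollection | None,
    disease: GeneSet,
    out: Path,
) -> dict:
    if pc is None or len(pc) == 0:
        return {"block": {"skipped": True, "reason": "no pathway collection supplied"}}
    background = GeneSet.from_iterable(
        "background", pc.all_genes() | set(net.graph.nodes)
    )
    enrich = pathmod.pathway_enrichment(
        pc,
        disease,
        background,
        score_threshold=cfg.enrichment_score_threshold,
        min_overlap=cfg.enrichment_min_overlap,
    )
    _write_tsv(
        out / "pathway_enrichment.tsv",
        ["pathway", "overlap", "pathway_size", "p_value", "score", "passes_filter"],
        [
            [e.pathway, e.overlap_count, e.pathway_size, f"{e.p_value:.4g}", f"{e.score:.3f}", e.passes_filter]
            for e in enrich
        ],
    )
    passing = [e.pathway for e in enrich if e.passes_filter]
    block: dict[str, Any] = {
        "n_pathways": len(pc),
        "n_enriched": len(passing),
        "enriched": sorted(passing),
        "enrichment": {
            e.pathway: {
                "overlap": e.overlap_count,
                "p_value": e.p_value,
                "score": e.score,
                "passes_filter": e.passes_filter,
            }
            for e in enrich
        },
    }
    crosstalk_results = None
    if len(passing) >= 3:
        filtered = pc.subset(passing)
        crosstalk_results = pathmod.crosstalk_all_pairs(
            filtered, net, alpha=cfg.crosstalk_alpha
        )
        _write_tsv(
            out / "pathway_crosstalk.tsv",
            [
                "pathway_a",
                "pathway_b",
                "n_common_nodes",
                "total_nodes",
                "n_common_links",
                "total_links",
                "p_nodes",
                "p_links",
                "q_nodes",
                "q_links",
                "p_min",
                "significant",
            ],
            [
                [
                    r.pathway_a,
                    r.pathway_b,
                    r.n_common_nodes,
                    r.total_nodes,
                    r.n_common_links,
                    r.total_links,
                    f"{r.p_nodes:.4g}",
                    f"{r.p_links:.4g}",
                    f"{r.q_nodes:.4g}",
                    f"{r.q_links:.4g}",
                    f"{r.p_min:.4g}",
                    r.significant,
                ]
                for r in crosstalk_results
            ],
        )
        scores = {e.pathway: min(e.score, 320.0) for e in enrich}
        graph = pathmod.crosstalk_graph(crosstalk_results, enrichment_scores=scores)
        write_graphml(graph, out / "pathway_crosstalk.graphml")
        block["crosstalk"] = {
            "n_pairs": len(crosstalk_results),
            "n_significant": sum(r.significant for r in crosstalk_results),
            "significant_pairs": sorted(
                [r.pathway_a, r.pathway_b] for r in crosstalk_results if r.significant
            ),
            "alpha": cfg.crosstalk_alpha,
        }
    else:
        block["crosstalk"] = {
            "skipped": True,
            "reason": f"only {len(passing)} enriched pathways (need >= 3)",
        }
    return {"block": block, "enrichment": enrich, "crosstalk": crosstalk_results}


def _stage_gwas(
    cfg: RunConfig,
    net: Network,
    sub: Network,
    disease: GeneSet,
    pathways_block: dict | None,
    pc: pathmod.PathwayCollection | None,
    out: Path,
) -> dict:
    if cfg.synthetic is not None:
        signal = GeneSet.from_iterable("subnetwork-signal", sub.graph.nodes)
        tables = [
            simulate.generate_gwas(
                net.sorted_nodes(),
                signal,
                beta_shape=cfg.synthetic.gwas_spec.beta_shape,
                seed=simulate.derive_seed(
                    cfg.synthetic.master_seed, simulate._STREAM_GWAS_BASE + j
                ),
                study_name=name,
                signal_fraction=cfg.synthetic.gwas_spec.signal_fraction,
            )
            for j, name in enumerate(cfg.synthetic.gwas_spec.study_names)
        ]
    elif cfg.gwas_paths:
        tables = [gwasmod.read_gwas_table(p) for p in cfg.gwas_paths]
    else:
        return {"block": {"skipped": True, "reason": "no GWAS tables supplied"}}
    study_a, study_b = tables[0], tables[1]
    joint = gwasmod.joint_significant_genes(
        sub.graph.nodes, study_a, study_b, alpha=cfg.gwas_alpha
    )
    universe = set(study_a.p_by_gene) & set(study_b.p_by_gene)
    seed = _derived_int_seed(cfg.master_seed, _STREAM_GWAS_RANDOMIZATION)
    empirical = gwasmod.enrichment_randomization(
        universe,
        set_size=sub.n_nodes,
        observed_count=len(joint),
        study_a=study_a,
        study_b=study_b,
        alpha=cfg.gwas_alpha,
        n_sets=cfg.n_random_sets,
        n_repeats=cfg.n_repeats,
        seed=seed,
    )
    result = gwasmod.nominate_candidates(sub, disease, joint, empirical)
    rows = [
        [
            g,
            f"{study_a.p_by_gene[g]:.4g}",
            f"{study_b.p_by_gene[g]:.4g}",
            sum(1 for nb in sub.graph.neighbors(g) if nb in disease.members),
        ]
        for g in sorted(result.novel_candidates)
    ]
    _write_tsv(
        out / "candidates.tsv",
        ["gene", "p_study_a", "p_study_b", "n_seed_neighbors"],
        rows,
    )
    for cand, ego in sorted(result.ego_subnetworks.items()):
        write_graphml(ego, out / f"ego_{cand}.graphml")
    block: dict[str, Any] = {
        "studies": [study_a.study_name, study_b.study_name],
        "universe_size": len(universe),
        "alpha": cfg.gwas_alpha,
        "n_joint_significant": len(result.joint_significant),
        "n_novel_candidates": len(result.novel_candidates),
        "novel_candidates": sorted(result.novel_candidates),
        "empirical_p_per_repeat": empirical,
        "n_random_sets": cfg.n_random_sets,
        "n_repeats": cfg.n_repeats,
        "randomization_seed": seed,
        "caveat": result.caveat,
    }
    # strategy 2: pathway-guided candidates from the top enriched pathway
    if pc is not None and pathways_block and pathways_block.get("enriched"):
        top = min(
            pathways_block["enriched"],
            key=lambda name: pathways_block["enrichment"][name]["p_value"],
        )
        try:
            guided = gwasmod.pathway_guided_candidates(net, pc.pathways[top], disease)
        except ValueError:
            guided = []
        block["pathway_guided"] = {"pathway": top, "candidates": guided[:20]}
    return {"block": block, "result": result}


# -- orchestrator ----------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the JSON report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "master_seed": cfg.master_seed,
        "stages": {},
    }
    completed: list[str] = []

    def _finish_manifest() -> None:
        with open(out / "MANIFEST", "w") as fh:
            for s in completed:
                fh.write(s + "\n")

    stage = "data"
    try:
        data = _stage_data(cfg, out)
        report["stages"]["data"] = data["block"]
        completed.append(stage)

        net = data["network"]
        gene_sets = data["gene_sets"]
        pc = data["pathways"]
        disease = gene_sets[cfg.disease_set]

        stage = "topology"
        topo_res = _stage_topology(cfg, net, gene_sets, out)
        report["stages"]["topology"] = topo_res["block"]
        completed.append(stage)

        stage = "subnet"
        sub_res = _stage_subnet(cfg, net, disease, out)
        report["stages"]["subnet"] = sub_res["block"]
        completed.append(stage)
        sub = sub_res["result"].subnetwork

        stage = "communities"
        comm_res = _stage_communities(cfg, sub, gene_sets, out)
        report["stages"]["communities"] = comm_res["block"]
        completed.append(stage)

        stage = "pathways"
        path_res = _stage_pathways(cfg, net, pc, disease, out)
        report["stages"]["pathways"] = path_res["block"]
        completed.append(stage)

        stage = "gwas"
        gwas_res = _stage_gwas(
            cfg, net, sub, disease, path_res.get("block"), pc, out
        )
        report["stages"]["gwas"] = gwas_res["block"]
        completed.append(stage)
    except Exception as exc:
        _finish_manifest()
        raise PipelineError(stage, exc) from exc

    _finish_manifest()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
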
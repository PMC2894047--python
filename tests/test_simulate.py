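import networkx as nx
import numpy as np
import pytest

from dgnet.network import GeneSet
from dgnet.simulate import (
    GwasSpec,
    PathwaySpec,
    SetSpec,
    SyntheticConfig,
    config_from_dict,
    default_config,
    derive_seed,
    generate_all,
    generate_gwas,
    generate_interactome,
    generate_pathways,
    plant_gene_set,
)


def _cfg(**kw):
    base = dict(n_nodes=1000, attachment_edges=3, triangle_closure_prob=0.0, master_seed=0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestInteractome:
    def test_edge_count_without_closure(self):
        cfg = _cfg()
        net = generate_interactome(cfg)
        n, m = cfg.n_nodes, cfg.attachment_edges
        assert net.n_edges == m * (n - m) + m * (m - 1) // 2
        assert nx.is_connected(net.graph)

    def test_heavy_tailed_degrees(self):
        net = generate_interactome(_cfg())
        degs = np.array([d for _, d in net.graph.degree()])
        assert degs.max() > 10 * np.median(degs)

    def test_closure_raises_clustering(self):
        low = generate_interactome(_cfg(triangle_closure_prob=0.0))
        high = generate_interactome(_cfg(triangle_closure_prob=0.9))
        assert nx.average_clustering(high.graph) > nx.average_clustering(low.graph)

    def test_single_attachment_gives_tree_plus_seed(self):
        cfg = _cfg(n_nodes=10, attachment_edges=1)
        net = generate_interactome(cfg)
        assert net.n_edges == 9 and nx.is_connected(net.graph)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_nodes=5)
        with pytest.raises(ValueError):
            SyntheticConfig(n_nodes=100, triangle_closure_prob=1.5)

    def test_deterministic_under_seed(self):
        a = generate_interactome(_cfg(master_seed=3))
        b = generate_interactome(_cfg(master_seed=3))
        assert a.sorted_edges() == b.sorted_edges()


@pytest.fixture(scope="module")
def net():
    return generate_interactome(_cfg(triangle_closure_prob=0.2))


class TestPlantGeneSet:
    def test_uniform_sampling_matches_network_mean(self, net):
        overall = 2 * net.n_edges / net.n_nodes
        set_means = []
        for i in range(50):
            gs = plant_gene_set(net, "u", 100, 0.0, False, seed=i)
            set_means.append(np.mean([net.graph.degree(g) for g in gs.members]))
        set_means = np.array(set_means)
        assert abs(set_means.mean() - overall) <= 2 * set_means.std()

    def test_hub_bias_raises_mean_degree(self, net):
        flat = plant_gene_set(net, "f", 100, 0.0, False, seed=5)
        biased = plant_gene_set(net, "b", 100, 2.0, False, seed=5)
        mean = lambda gs: np.mean([net.graph.degree(g) for g in gs.members])
        assert mean(biased) > mean(flat)

    def test_full_size_returns_all_nodes(self, net):
        gs = plant_gene_set(net, "all", net.n_nodes, 3.0, False, seed=0)
        assert gs.members == frozenset(net.graph.nodes)

    def test_oversized_rejected(self, net):
        with pytest.raises(ValueError):
            plant_gene_set(net, "x", net.n_nodes + 1, 0.0, False, seed=0)

    def test_clique_planting_raises_internal_edges(self, net):
        plain = plant_gene_set(net, "p", 120, 1.0, False, seed=11)
        clustered = plant_gene_set(net, "c", 120, 1.0, True, seed=11)
        internal = lambda gs: net.graph.subgraph(gs.members).number_of_edges()
        assert internal(clustered) > internal(plain)


class TestPathways:
    def test_jaccard_zero_means_disjoint(self, net):
        spec = PathwaySpec(count=3, size_range=(20, 30), overlap_pairs=((0, 1, 0.0),))
        pc = generate_pathways(net, spec, seed=0)
        assert not (pc.pathways["PATHWAY-00"] & pc.pathways["PATHWAY-01"])

    def test_jaccard_one_means_identical(self, net):
        spec = PathwaySpec(count=3, size_range=(25, 25), overlap_pairs=((0, 1, 1.0),))
        pc = generate_pathways(net, spec, seed=0)
        assert pc.pathways["PATHWAY-00"] == pc.pathways["PATHWAY-01"]

    def test_intermediate_jaccard_within_tolerance(self, net):
        spec = PathwaySpec(count=4, size_range=(40, 40), overlap_pairs=((0, 1, 0.3),))
        pc = generate_pathways(net, spec, seed=1)
        a, b = pc.pathways["PATHWAY-00"], pc.pathways["PATHWAY-01"]
        jac = len(a & b) / len(a | b)
        assert abs(jac - 0.3) <= 0.1

    def test_seeded_pathways_contain_disease_genes(self, net):
        gs = plant_gene_set(net, "disease", 100, 0.5, False, seed=2)
        spec = PathwaySpec(
            count=4, size_range=(40, 40), seed_set="disease", seed_fraction=0.25, seeded_count=2
        )
        pc = generate_pathways(net, spec, seed=3, gene_sets={"disease": gs})
        assert len(pc.pathways["PATHWAY-00"] & gs.members) >= 8
        assert len(pc.pathways["PATHWAY-03"] & gs.members) <= 3

    def test_infeasible_overlap_rejected(self, net):
        spec = PathwaySpec(count=2, size_range=(20, 30), overlap_pairs=((0, 1, 1.5),))
        with pytest.raises(ValueError):
            generate_pathways(net, spec, seed=0)


class TestGwas:
    genes = [f"G{i:05d}" for i in range(5000)]
    signal = GeneSet.from_iterable("signal", genes[:1000])

    def test_beta_one_matches_null(self):
        t = generate_gwas(self.genes, self.signal, beta_shape=1.0, seed=0)
        sig_p = [t.p_by_gene[g] for g in self.signal.members]
        # Beta(1,1) is Uniform: the signal block should not be enriched
        assert abs(np.mean([p < 0.05 for p in sig_p]) - 0.05) < 0.03

    def test_beta_small_shape_concentrates_signal(self):
        t = generate_gwas(self.genes, self.signal, beta_shape=0.1, seed=1)
        frac = np.mean([t.p_by_gene[g] < 0.05 for g in self.signal.members])
        assert abs(frac - 0.05**0.1) <= 0.05  # P(p < t) = t^a

    def test_studies_independent_for_null_genes(self):
        a = generate_gwas(self.genes, self.signal, 0.1, seed=2, study_name="a")
        b = generate_gwas(self.genes, self.signal, 0.1, seed=3, study_name="b")
        null_genes = self.genes[1000:]
        pa = np.array([a.p_by_gene[g] for g in null_genes])
        pb = np.array([b.p_by_gene[g] for g in null_genes])
        assert abs(np.corrcoef(pa, pb)[0, 1]) < 0.1

    def test_signal_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            generate_gwas(self.genes[:10], self.signal, 0.1, seed=0)


class TestDeterminism:
    def test_full_fixture_is_pure_function_of_config(self):
        cfg = SyntheticConfig(
            n_nodes=300,
            attachment_edges=2,
            triangle_closure_prob=0.3,
            set_specs=(SetSpec("disease-like", 30, 0.5, False),),
            pathway_spec=PathwaySpec(count=3, size_range=(10, 15)),
            gwas_spec=GwasSpec(signal_set="disease-like"),
            master_seed=9,
        )
        a, b = generate_all(cfg), generate_all(cfg)
        assert a.network.sorted_edges() == b.network.sorted_edges()
        assert {k: v.members for k, v in a.gene_sets.items()} == {
            k: v.members for k, v in b.gene_sets.items()
        }
        assert a.pathways.pathways == b.pathways.pathways
        for ta, tb in zip(a.gwas, b.gwas):
            assert ta.p_by_gene == tb.p_by_gene

    def test_config_roundtrip_from_dict(self):
        cfg = default_config(4)
        raw = {
            "n_nodes": cfg.n_nodes,
            "attachment_edges": cfg.attachment_edges,
            "triangle_closure_prob": cfg.triangle_closure_prob,
            "set_specs": [
                {
                    "name": s.name,
                    "size": s.size,
                    "degree_bias_exponent": s.degree_bias_exponent,
                    "clique_planting": s.clique_planting,
                }
                for s in cfg.set_specs
            ],
            "pathway_spec": {
                "count": cfg.pathway_spec.count,
                "size_range": list(cfg.pathway_spec.size_range),
                "overlap_pairs": [list(t) for t in cfg.pathway_spec.overlap_pairs],
                "seed_set": cfg.pathway_spec.seed_set,
                "seed_fraction": cfg.pathway_spec.seed_fraction,
                "seeded_count": cfg.pathway_spec.seeded_count,
            },
            "master_seed": 4,
        }
        assert config_from_dict(raw).set_specs == cfg.set_specs

    def test_derived_seeds_are_stream_stable(self):
        a = derive_seed(1, 100).generate_state(4)
        b = derive_seed(1, 100).generate_state(4)
        c = derive_seed(1, 101).generate_state(4)
        assert (a == b).all() and not (a == c).all()
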
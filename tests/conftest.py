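import pytest

from dgnet import simulate as sim
from dgnet import steiner as steinermod


@pytest.fixture(scope="session")
def default_cfg():
    return sim.default_config(master_seed=0)


@pytest.fixture(scope="session")
def interactome(default_cfg):
    return sim.generate_interactome(default_cfg)


@pytest.fixture(scope="session")
def gene_sets(default_cfg, interactome):
    out = {}
    for i, spec in enumerate(default_cfg.set_specs):
        out[spec.name] = sim.plant_gene_set(
            interactome,
            spec.name,
            spec.size,
            spec.degree_bias_exponent,
            spec.clique_planting,
            seed=sim.derive_seed(default_cfg.master_seed, 100 + i),
        )
    return out


@pytest.fixture(scope="session")
def disease_subnet(interactome, gene_sets):
    return steinermod.steiner_subnetwork(
        interactome, gene_sets["disease-like"]
    ).subnetwork
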
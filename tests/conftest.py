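import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polysize as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

MMA_SMILES = "*CC(*)(C)C(=O)OC"


@pytest.fixture(scope="session")
def mma_unit():
    return ps.parse_repeat_unit(MMA_SMILES, name="methyl methacrylate")


@pytest.fixture(scope="session")
def spec():
    return ps.default_feature_spec()


@pytest.fixture(scope="session")
def cyclic_mma(mma_unit, spec):
    return ps.build_cyclic_polymer(mma_unit, 10, spec)


def random_graph(rng, n_max=12, dim=5):
    """Arbitrary featurized graph for convolution oracles (not a molecule)."""
    n = int(rng.integers(1, n_max + 1))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((i, j))
    edges = np.array(edges, dtype=int).reshape(-1, 2)
    H0 = rng.normal(size=(n, dim))
    return ps.MolecularGraph(
        n_nodes=n,
        edges=edges,
        H0=H0,
        unit_index=np.zeros(n, dtype=int),
        atom_index=np.arange(n),
        n_units=1,
        unit_size=n,
        cyclic=False,
    )


@pytest.fixture(scope="session")
def tiny_model_config():
    """Small architecture for fast end-to-end training tests."""
    return ps.ModelConfig(
        conv_dims=(32, 32),
        fc_dims=(32, 16),
        lr=3e-3,
        max_epochs=300,
        patience=60,
        batch_size=64,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Reduced synthetic study: 4 units x 2 Dp x 3 conc x 2 surf x 9 = 432."""
    battery = {
        k: ps.METHACRYLATE_BATTERY[k]
        for k in (
            "methyl methacrylate",
            "butyl methacrylate",
            "phenyl methacrylate",
            "isobornyl methacrylate",
        )
    }
    cfg = ps.SynthConfig(
        battery=battery,
        dp_levels=(53.0, 420.0),
        conc_levels_gL=(1.0, 10.0, 30.0),
        seed=11,
    )
    return ps.generate_clean_dataset(cfg)
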
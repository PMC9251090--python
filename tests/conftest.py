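import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact planted-signal dataset shared by end-to-end tests."""
    from genesieve.enrichment import build_matrix
    from genesieve.synthetic import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        n_genes=250,
        n_terms_per_namespace={"BP": 20, "CC": 8, "MF": 8, "PATHWAY": 6},
        term_size_range=(8, 20),
        mean_degree=8.0,
        n_positive=30,
        n_causal_terms=3,
        effect_strength=0.9,
        seed=11,
    )
    ds = generate_dataset(cfg)
    mat = build_matrix(ds.catalog, ds.network)
    y = np.array([1 if g in ds.positives else 0 for g in mat.genes])
    return cfg, ds, mat, y
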
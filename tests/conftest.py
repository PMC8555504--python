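import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from trinet.synthetic_data import GeneratorConfig, generate_dataset

SMALL = GeneratorConfig(
    n_studies=3,
    samples_per_group=10,
    n_genes=400,
    n_mirnas=60,
    n_tfs=20,
    n_de_genes=30,
    n_de_mirnas=16,
    n_triads=4,
    n_loops=2,
    n_decoys_per_class=1,
    n_filler_tf_edges=25,
    n_filler_target_edges=60,
    ppi_n_background=30,
    planted_module_sizes=(6, 5),
)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic screen shared across read-only tests."""
    return generate_dataset(SMALL, seed=11)
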
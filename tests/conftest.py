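import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import subtypeflow as sf
from subtypeflow.pipeline import benchmark_config

settings.register_profile(
    "det",
    settings(max_examples=30, derandomize=True, deadline=None,
             suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def bench():
    """Standard synthetic benchmark (exact-zero normal sparse block) plus a
    full-length BRPCA decomposition of it (K=10, 200+100 sweeps)."""
    spec = sf.SyntheticSpec(seed=1)
    em, truth = sf.generate_dataset(spec)
    hp = sf.BRPCAHyperparams.for_shape(em.n_genes, em.n_samples, K=10, seed=2)
    dec = sf.decompose(em.values, hp)
    return em, truth, hp, dec


@pytest.fixture(scope="session")
def pipeline_bench():
    """Full pipeline run on the end-to-end benchmark (weak normal signature)."""
    spec, cfg = benchmark_config(seed=5)
    em, truth = sf.generate_dataset(spec)
    result = sf.run_pipeline(em, cfg)
    return em, truth, cfg, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
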
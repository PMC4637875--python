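from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_150)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Small end-to-end synthetic bundle shared by pipeline tests."""
    from mirderep.pipeline import make_demo

    out = tmp_path_factory.mktemp("demo")
    paths = make_demo(seed=42, out_dir=out, n_reads=4_000, n_genes=4_000)
    return paths
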
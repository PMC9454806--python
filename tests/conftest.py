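import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_cm(rng):
    """Random 12-gene x 8-cell count matrix with two mito genes."""
    from veinoise import CountMatrix

    genes = ["MT-A", "MT-B"] + [f"G{i}" for i in range(10)]
    barcodes = [f"cell{i}" for i in range(8)]
    counts = rng.poisson(4.0, size=(12, 8))
    return CountMatrix(genes, barcodes, counts)
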
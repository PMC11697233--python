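import numpy as np
import pytest

from abersim import OpticalConfig, PhantomSpec, blur_with_psf, generate_phantom, psf_from_pupil
from abersim.benchmark import BenchmarkConfig, run_restoration_benchmark

SMALL_COUNTS = {"dots": 8, "lines": 4, "circles": 2, "spheres": 2, "shells": 2}


@pytest.fixture(scope="session")
def cfg32():
    return OpticalConfig(grid_shape=(32, 32, 32))


@pytest.fixture(scope="session")
def ipsf32(cfg32):
    return psf_from_pupil(cfg32)


@pytest.fixture(scope="session")
def phantom32():
    spec = PhantomSpec(grid_shape=(32, 32, 32), counts=dict(SMALL_COUNTS), rng_seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def blurred32(phantom32, ipsf32):
    return blur_with_psf(phantom32, ipsf32)


@pytest.fixture(scope="session")
def benchmark_result():
    """One full restoration-benchmark run shared by the ordering tests."""
    return run_restoration_benchmark(BenchmarkConfig(), rng_seed=0)
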
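import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import colposim as cs

settings.register_profile(
    "det",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def lab_system():
    return cs.emission_filtering_lab()


@pytest.fixture(scope="session")
def clinical_system():
    return cs.clinical_dual_lctf()


@pytest.fixture(scope="session")
def small_grid():
    return cs.make_grid(650, 695, 5, "closed")  # 10 bands


@pytest.fixture()
def small_cube(small_grid):
    rng = np.random.default_rng(42)
    data = rng.integers(0, 1024, size=(8, 8, small_grid.n_bands), dtype=np.uint16)
    return cs.HSCube(
        data=data,
        grid=small_grid,
        bit_depth=10,
        exposure_ms=np.full(small_grid.n_bands, 100.0),
        metadata={"origin": "test"},
    )
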
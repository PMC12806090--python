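import numpy as np
import pytest

from stmodules.mesh_basis import SpotSet, build_basis_system, build_mesh


@pytest.fixture
def right_triangle_spots():
    return SpotSet(
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        spot_ids=("a", "b", "c"),
    )


@pytest.fixture
def right_triangle_mesh(right_triangle_spots):
    return build_mesh(right_triangle_spots)


@pytest.fixture
def unit_square_spots():
    return SpotSet(
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        spot_ids=("s0", "s1", "s2", "s3"),
    )


@pytest.fixture
def grid3x3_spots():
    xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return SpotSet(coords=coords, spot_ids=tuple(f"g{i}" for i in range(9)))


@pytest.fixture
def small_random_spots():
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 1, size=(12, 2))
    return SpotSet(coords=coords, spot_ids=tuple(f"r{i}" for i in range(12)))


@pytest.fixture
def small_basis(small_random_spots):
    return build_basis_system(small_random_spots)
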
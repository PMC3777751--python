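import numpy as np
import pytest
from hypothesis import settings

from aslprodrome.phantom import PhantomSpec, make_ground_truth, simulate_subject_series

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


SMALL_GRID = (32, 32, 16)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced-grid phantom used throughout: native voxel size, 16 pairs."""
    return PhantomSpec(grid_shape=SMALL_GRID, n_volumes=33, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_ground_truth(small_spec)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noise-free, drift-free phantom for exact-recovery tests."""
    return PhantomSpec(
        grid_shape=SMALL_GRID, n_volumes=33, noise_sd=0.0, drift_amplitude=0.0, seed=5
    )


@pytest.fixture(scope="session")
def clean_truth(clean_spec):
    return make_ground_truth(clean_spec)


@pytest.fixture(scope="session")
def clean_series(clean_spec, clean_truth):
    return simulate_subject_series(clean_spec, clean_truth)


def brute_force_cc(maps: np.ndarray, gm_mask: np.ndarray, kept: np.ndarray) -> np.ndarray:
    """Independent leave-one-out correlation oracle: explicit python loops,
    no shared code with the implementation."""
    kept_idx = [i for i in range(maps.shape[3]) if kept[i]]
    cc = np.zeros(maps.shape[3])
    for i in range(maps.shape[3]):
        others = [j for j in kept_idx if j != i] if kept[i] else kept_idx
        acc = np.zeros(maps.shape[:3])
        for j in others:
            acc += maps[..., j]
        ref = acc / len(others)
        a = maps[..., i][gm_mask]
        b = ref[gm_mask]
        cc[i] = np.corrcoef(a, b)[0, 1]
    return cc
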
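import numpy as np
import pytest

from lusrecon import PhantomSpec, generate_phantom, simulate_sweep


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: deterministic and order-independent
    return np.random.default_rng(12345)


# A small, quiet phantom reused by unit tests: short sweep, no pose noise.
SMALL_SPEC = PhantomSpec(
    seed=11,
    n_frames=12,
    image_shape=(120, 96),
    pose_noise_rot_deg=0.0,
    pose_noise_trans_mm=0.0,
)


@pytest.fixture(scope="session")
def small_truth():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_sim(small_truth):
    return simulate_sweep(small_truth)


# Noise-free variant for exact forward/inverse checks.
CLEAN_SPEC = PhantomSpec(
    seed=7,
    n_frames=6,
    image_shape=(120, 96),
    speckle_strength=0.0,
    noise_sigma=0.0,
    smooth_sigma=0.0,
    pose_noise_rot_deg=0.0,
    pose_noise_trans_mm=0.0,
)


@pytest.fixture(scope="session")
def clean_truth():
    return generate_phantom(CLEAN_SPEC)


@pytest.fixture(scope="session")
def clean_sim(clean_truth):
    return simulate_sweep(clean_truth)
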
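import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0


@pytest.fixture(scope="session")
def noisy_sphere_phantom():
    """A noisy spherical nut at 0.15 mm voxels with closed-form truth."""
    from nutct import phantom

    vol, truth = phantom.make_spherical_nut(
        outer_radius_mm=8.0,
        shell_thickness_mm=1.2,
        kernel_radius_mm=5.0,
        voxel_size_mm=0.15,
        noise_sigma=5.0,
        seed=42,
    )
    return vol, truth


@pytest.fixture(scope="session")
def clean_sphere_phantom():
    """A noise-free spherical nut at 0.15 mm voxels."""
    from nutct import phantom

    return phantom.make_spherical_nut(
        outer_radius_mm=8.0,
        shell_thickness_mm=1.2,
        kernel_radius_mm=5.0,
        voxel_size_mm=0.15,
        noise_sigma=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_scan():
    """A 4-nut batch scan at 0.4 mm voxels (fast end-to-end fixture)."""
    from nutct import phantom

    return phantom.make_scan(n_nuts=4, voxel_size_mm=0.4, seed=5)
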
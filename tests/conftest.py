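import numpy as np
import pytest

from scarchar.phantom import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A fast low-resolution phantom spec for simulation-heavy tests."""
    params = dict(
        grid_size=48,
        n_slices=4,
        pixel_spacing_mm=2.0,
        endo_radius_mm=10.0,
        epi_radius_mm=16.0,
        scar_slice_range=(0, 4),
        n_contour_vertices=128,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default-geometry phantom shared across read-only tests."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(noise_sd=5.0, seed=7))


def circle(cx: float, cy: float, r: float, n: int = 360) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
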
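import numpy as np
import pytest

from brainsegeval.phantom import PhantomSpec, generate_phantom
from brainsegeval.volumes import Component, ComponentMask

ANISO = (0.96, 0.96, 3.0)


def small_spec(seed: int = 1) -> PhantomSpec:
    """A scaled-down phantom spec that keeps the anisotropic geometry but
    generates in milliseconds."""
    return PhantomSpec(
        dims=(48, 48, 24),
        spacing=ANISO,
        center_frac=(0.5, 0.5, 0.55),
        icv_semiaxes=(20.0, 21.0, 17.0),
        gm_semiaxes=(17.0, 18.0, 14.0),
        wm_semiaxes=(13.0, 14.0, 10.0),
        ventricle_semiaxes=(3.0, 6.0, 4.0),
        ventricle_offset_mm=4.5,
        basal_ganglia_semiaxes=(2.5, 4.0, 3.0),
        basal_ganglia_offset_mm=9.0,
        n_wml=2,
        wml_radius_mm=(1.5, 2.5),
        hindbrain_semiaxes=(10.0, 8.0, 6.0),
        hindbrain_center_frac=(0.5, 0.35, 0.12),
        seed=seed,
    )


@pytest.fixture(scope="session")
def phantom_small():
    return generate_phantom(small_spec(seed=1))


def random_mask(shape, density, seed, spacing=ANISO, component=Component.GM) -> ComponentMask:
    rng = np.random.default_rng(seed)
    grid = rng.random(shape) < density
    return ComponentMask(grid=grid, spacing=spacing, component=component)


def make_mask(grid, spacing=ANISO, component=Component.GM) -> ComponentMask:
    return ComponentMask(grid=np.asarray(grid, dtype=bool), spacing=spacing, component=component)
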
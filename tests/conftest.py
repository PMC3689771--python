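import numpy as np
import pytest

from cmbdetect import (
    PhantomSpec,
    PlaneSpec,
    SphereSpec,
    TubeSpec,
    VoxelVolume,
    generate,
)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact phantom with one sphere, one oblique tube and one plane."""
    spec = PhantomSpec(
        extents=(64, 64, 24),
        spheres=(SphereSpec((30.0, 30.0, 36.0), 5.0, 0.7),),
        tubes=(
            TubeSpec(
                ((48.0, 14.0, 9.0), (44.0, 20.0, 27.0), (40.0, 26.0, 45.0), (36.0, 32.0, 63.0)),
                1.2,
                0.8,
            ),
        ),
        planes=(PlaneSpec((12.0, 32.0, 33.0), (1.0, 0.0, 0.0), 2.0, 0.6),),
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def sphere_only_phantom():
    """Single clean 5-mm sphere on an isotropic grid, no noise."""
    spec = PhantomSpec(
        extents=(32, 32, 32),
        spacing_mm=(1.0, 1.0, 1.0),
        noise_sigma=0.0,
        texture_amplitude=0.0,
        dark_structure_depth=0.0,
        spheres=(SphereSpec((15.0, 15.0, 15.0), 5.0, 0.8),),
        seed=3,
    )
    return generate(spec)


@pytest.fixture()
def flat_volume():
    return VoxelVolume(np.full((8, 8, 8), 100.0), (1.0, 1.0, 1.0))


@pytest.fixture()
def full_mask():
    def _make(shape, spacing=(1.0, 1.0, 1.0)):
        return VoxelVolume(np.ones(shape, dtype=bool), spacing)

    return _make
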
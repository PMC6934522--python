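import numpy as np
import pytest

from protonrbe import (
    ModelParams,
    PhantomSpec,
    Quantity,
    ROIMask,
    VoxelGrid,
    generate_plan,
    single_field_spec,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def bundle():
    """Default seeded three-field phantom, generated once per session."""
    return generate_plan(PhantomSpec())


@pytest.fixture(scope="session")
def sf_bundle():
    """Single lateral-field phantom for falloff / range-extension checks."""
    return generate_plan(single_field_spec())


@pytest.fixture
def small_grid():
    """A 2x3x4 dose grid with distinct values, 2 mm voxels."""
    return VoxelGrid(
        dims=(2, 3, 4),
        spacing_mm=(2.0, 2.0, 2.0),
        origin_mm=(1.0, 1.0, 1.0),
        values=np.arange(24, dtype=float),
        quantity=Quantity.DOSE,
    )


@pytest.fixture
def full_mask(small_grid):
    return ROIMask.from_grid("all", small_grid, np.ones(small_grid.dims, dtype=bool))
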
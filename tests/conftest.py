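import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from firebreaks import (
    CAParams,
    LandscapeGrid,
    generate_artificial_forest,
    generate_heterogeneous_landscape,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def params() -> CAParams:
    return CAParams()


@pytest.fixture
def forest50() -> LandscapeGrid:
    return generate_artificial_forest(50, seed=42)


@pytest.fixture
def torus3_half() -> LandscapeGrid:
    """3x3 periodic grid, every cell emptiness 0.5 (all spread probs 0.5)."""
    return make_simple_grid(np.full((3, 3), 0.5))


def make_simple_grid(emptiness, boundary="periodic") -> LandscapeGrid:
    emptiness = np.asarray(emptiness, dtype=float)
    return LandscapeGrid(
        n_rows=emptiness.shape[0],
        n_cols=emptiness.shape[1],
        boundary=boundary,
        model_kind="simple",
        burn_state=np.zeros(emptiness.shape, dtype=np.int8),
        emptiness=emptiness,
    )


def make_full_grid(
    type_label,
    density_label,
    elevation=None,
    params: CAParams | None = None,
    boundary="absorbing",
    fuel_mask=None,
) -> LandscapeGrid:
    params = params or CAParams()
    type_label = np.asarray(type_label, dtype=object)
    density_label = np.asarray(density_label, dtype=object)
    shape = type_label.shape
    if elevation is None:
        elevation = np.zeros(shape)
    if fuel_mask is None:
        fuel_mask = np.ones(shape, dtype=bool)
    type_effect = np.zeros(shape)
    density_effect = np.zeros(shape)
    for (r, c), t in np.ndenumerate(type_label):
        if fuel_mask[r, c]:
            type_effect[r, c] = params.type_effect_table[t]
            density_effect[r, c] = params.density_effect_table[density_label[r, c]]
    return LandscapeGrid(
        n_rows=shape[0],
        n_cols=shape[1],
        boundary=boundary,
        model_kind="full",
        burn_state=np.zeros(shape, dtype=np.int8),
        type_effect=type_effect,
        density_effect=density_effect,
        elevation=np.asarray(elevation, dtype=float),
        fuel_mask=np.asarray(fuel_mask, dtype=bool),
        type_label=type_label,
        density_label=density_label,
        cell_side=params.cell_side,
    )


@pytest.fixture
def hetero30() -> LandscapeGrid:
    return generate_heterogeneous_landscape(30, seed=5)
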
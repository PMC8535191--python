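"""Shared fixtures: one synthetic world and its fitted-training ingredients.

Session scope keeps the expensive pieces (world generation, cliff
delineation, background extraction) to a single computation.
"""

import numpy as np
import pytest

from cliffsdm import (
    SyntheticWorldSpec,
    TrueModel,
    delineate_cliffs,
    distance_raster,
    gen_world,
    sample_background,
    sample_presences,
    presence_values,
)

# desk-scale delineation settings used throughout the suite
TRANSECT_KW = dict(spacing_m=100.0, length_m=300.0, step_m=10.0)


@pytest.fixture(scope="session")
def world():
    return gen_world(SyntheticWorldSpec(seed=1))


@pytest.fixture(scope="session")
def cliff_points(world):
    return delineate_cliffs(world.dtm, world.coastline, **TRANSECT_KW)


@pytest.fixture(scope="session")
def stack(world, cliff_points):
    template = next(iter(world.climate.values()))
    dist = distance_raster(template, cliff_points)
    return world.present_stack(dist)


@pytest.fixture(scope="session")
def true_model():
    return TrueModel()


@pytest.fixture(scope="session")
def training_data(stack, true_model):
    """m=500 presences from the known truth, 5000 background, region matrix."""
    occ = sample_presences(true_model, stack, 500, seed=11)
    pres = presence_values(stack, occ.coords())
    _, _, bg = sample_background(stack, 5000, seed=12)
    rows, cols = np.nonzero(stack.valid_mask())
    region = stack.values_at_cells(rows, cols)
    return {"occ": occ, "pres": pres, "bg": bg, "region": region}
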
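import numpy as np
import pandas as pd
import pytest

from bearconflict.raster import GridRaster, extract_values, make_points
from bearconflict.rspf import build_design
from bearconflict.sampling import BackgroundSpec, generate_background
from bearconflict.simulate import (CovariateDef, LandscapeSpec, TrueModel,
                                   full_synthetic_study, simulate_conflicts)


@pytest.fixture(scope="session")
def std_spec():
    """Three standardised continuous covariates plus a 4-class cover layer."""
    return LandscapeSpec(
        n_rows=48, n_cols=48, cell_size=50.0, seed=42,
        covariate_defs=(
            CovariateDef("c0", 5, 0.0, 1.0),
            CovariateDef("c1", 5, 0.0, 1.0),
            CovariateDef("c2", 3, 0.0, 1.0),
        ),
        n_cover_classes=4,
    )


@pytest.fixture(scope="session")
def std_truth():
    # strong selection so the true w spans most of (0, 1): well identified
    return TrueModel(0.0, {"c0": 1.0, "c1": -0.8, "c2": 0.6},
                     cover_effects={1: -0.7})


@pytest.fixture(scope="session")
def study(std_spec, std_truth):
    return full_synthetic_study(std_spec, std_truth)


def make_use_availability(study, n_used, seed, ratio=5, buffer=0.0):
    """Used points from the true model plus a uniform availability sample."""
    used = simulate_conflicts(study, n_used, seed=seed)
    bg = generate_background(study.region_mask, used,
                             BackgroundSpec(buffer, ratio, seed=seed + 1))
    bg = extract_values(study.stack, bg)
    return pd.concat([used, bg], ignore_index=True)


@pytest.fixture(scope="session")
def use_avail_points(study):
    return make_use_availability(study, 400, seed=7)


@pytest.fixture(scope="session")
def design(use_avail_points):
    return build_design(use_avail_points, ["c0", "c1", "c2"], cover="cover")


@pytest.fixture
def bool_raster():
    def _make(mask, cell_size=50.0, origin=(0.0, 0.0)):
        return GridRaster(np.asarray(mask, dtype=bool), cell_size, origin,
                          kind="boolean")
    return _make


@pytest.fixture
def random_points():
    def _make(n, seed, extent=(0.0, 2400.0, -2400.0, 0.0), label=1):
        rng = np.random.default_rng(seed)
        x = rng.uniform(extent[0], extent[1], n)
        y = rng.uniform(extent[2], extent[3], n)
        return make_points(x, y, np.full(n, label))
    return _make
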
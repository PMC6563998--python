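"""Shared fixtures and instance factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from islereserve.optimizer import ProblemSpec
from islereserve.raster import BinaryGrid, Grid, StudyArea


def full_area(nrows: int, ncols: int) -> StudyArea:
    """A rectangular study area with every cell analyzable."""
    mask = np.zeros((nrows, ncols), dtype=bool)
    return StudyArea(mask=BinaryGrid(values=np.ones((nrows, ncols)), nodata_mask=mask))


def binary(values, nodata=None) -> BinaryGrid:
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, bool) if nodata is None else np.asarray(nodata, bool)
    return BinaryGrid(values=values, nodata_mask=mask)


def grid(values, nodata=None) -> Grid:
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, bool) if nodata is None else np.asarray(nodata, bool)
    return Grid(values=values, nodata_mask=mask)


def random_binary(rng, shape, density=0.4) -> BinaryGrid:
    pres = rng.random(shape) < density
    if not pres.any():
        pres[tuple(rng.integers(0, s) for s in shape)] = True
    return binary(pres.astype(float))


def random_minset_instance(
    seed: int, nrows=5, ncols=5, n_species=4, target=0.5, **spec_kw
) -> ProblemSpec:
    """A random small reserve-selection instance on a full rectangle."""
    rng = np.random.default_rng(seed)
    area = full_area(nrows, ncols)
    layers = {
        f"sp{s}": random_binary(rng, (nrows, ncols), density=rng.uniform(0.2, 0.6))
        for s in range(n_species)
    }
    return ProblemSpec(species_layers=layers, study_area=area, target=target, **spec_kw)


@pytest.fixture(scope="session")
def desk_bundle():
    """One desk-scale synthetic study shared across read-only tests."""
    from islereserve.synth import generate_study

    return generate_study(seed=7)
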
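import numpy as np
import pytest

from scenplan.landcover import LandCoverGrid, default_registry
from scenplan.reserve import SelectionProblem
from scenplan.synthetic import (
    LandscapeConfig,
    ProtectedAreaMask,
    generate_landscape,
    generate_protected_areas,
    generate_species,
    make_pu_grid,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def landscape():
    """32x32 grid of 1 km cells (1,024 km^2), default class mix."""
    return generate_landscape(LandscapeConfig(rows=32, cols=32), seed=11)


@pytest.fixture(scope="session")
def pas(landscape):
    return generate_protected_areas(landscape, 0.15, seed=3)


@pytest.fixture(scope="session")
def pu_grid(landscape):
    return make_pu_grid(landscape, pu_area=1.0)


@pytest.fixture(scope="session")
def species_pool(landscape):
    return generate_species(8, landscape, atlas_block=8, seed=7)


def uniform_grid(code, shape=(8, 8), cell_size=1.0, registry=None):
    reg = registry or default_registry()
    return LandCoverGrid(np.full(shape, code, dtype=np.int64), cell_size, reg)


def make_problem(
    n_pu,
    amounts,
    targets,
    spf,
    cost=None,
    status=None,
    edges=(),
    outer=None,
    blm=0.0,
):
    """Hand-built selection problem with PU ids 1..n_pu."""
    amounts = np.asarray(amounts, dtype=float)
    n_sp = amounts.shape[1]
    return SelectionProblem(
        pu_ids=np.arange(1, n_pu + 1),
        species_ids=[f"s{i + 1}" for i in range(n_sp)],
        cost=np.ones(n_pu) if cost is None else np.asarray(cost, float),
        amounts=amounts,
        targets=np.asarray(targets, float),
        spf=np.asarray(spf, float),
        status=np.zeros(n_pu, np.int8) if status is None else np.asarray(status, np.int8),
        edge_a=np.array([e[0] for e in edges], np.int64),
        edge_b=np.array([e[1] for e in edges], np.int64),
        edge_len=np.array([e[2] for e in edges], float),
        outer_len=np.zeros(n_pu) if outer is None else np.asarray(outer, float),
        blm=blm,
    )


@pytest.fixture
def empty_mask(landscape):
    return ProtectedAreaMask(np.zeros(landscape.shape, dtype=bool))
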
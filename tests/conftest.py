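import numpy as np
import pytest

from protustim import (
    CONDUCTOR,
    GROUND,
    LIQUID,
    STIM,
    BoundarySpec,
    LabeledGrid,
    MaterialProps,
    StructureConfig,
    solve,
)


@pytest.fixture(scope="session")
def materials():
    return MaterialProps()


def make_two_plate(n_liquid=10, h_um=1.0, nxy=3) -> LabeledGrid:
    """Parallel-plate stack: conductor | n_liquid liquid voxels | conductor."""
    labels = np.full((nxy, nxy, n_liquid + 2), LIQUID, dtype=np.uint8)
    eids = np.zeros_like(labels)
    labels[:, :, 0] = CONDUCTOR
    eids[:, :, 0] = STIM
    labels[:, :, -1] = CONDUCTOR
    eids[:, :, -1] = GROUND
    return LabeledGrid(h_um, labels, eids)


@pytest.fixture(scope="session")
def two_plate_ideal(materials):
    grid = make_two_plate()
    return solve(grid, materials, BoundarySpec(ideal=True))


@pytest.fixture(scope="session")
def small_config():
    """Smallest fabricated configuration — cheap to voxelize and solve."""
    return StructureConfig(60.0, 40.0, 8.0)


@pytest.fixture(scope="session")
def small_g1_solution(small_config, materials):
    """Solved single-mushroom structure on the small configuration."""
    import dataclasses

    from protustim import build_structure

    cfg = dataclasses.replace(small_config, n_protuberances=1)
    grid = build_structure(cfg, spacing_um=2.0, margin_um=60.0)
    return solve(grid, materials, BoundarySpec(ideal=True))
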
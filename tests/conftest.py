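import numpy as np
import pytest

from ctqpr import AIFParams, make_phantom, simulate_dynamic_ctp
from ctqpr.core import Branch, CoronaryTree, Seed


@pytest.fixture(scope="session")
def default_aif_params():
    return AIFParams(amplitude=400.0, t0=6.0, alpha=3.0, beta=1.5)


@pytest.fixture(scope="session")
def uniform_times():
    """30 frames at one beat per 0.75 s (80 bpm)."""
    return 0.75 * np.arange(30)


@pytest.fixture(scope="session")
def small_phantom():
    """24^3 phantom, 4 territories (LAD + D1, LCX, RCA), LAD hypoperfused."""
    return make_phantom(
        grid_shape=(24, 24, 24),
        spacing=(3.0, 3.0, 3.0),
        seed=7,
        ffr_by_vessel={"LAD": 0.65, "LCX": 0.92, "RCA": 0.95},
    )


@pytest.fixture(scope="session")
def noiseless_acquisition(small_phantom):
    series, aif_times, aif_values = simulate_dynamic_ctp(
        small_phantom, noise_sd=0.0, seed=1
    )
    return series, aif_times, aif_values


def straight_tree(n_branches=2, spacing_mm=10.0, length=60.0, n_points=7, seeds=()):
    """Parallel straight branches along z, separated along x."""
    branches = []
    for i in range(n_branches):
        z = np.linspace(5.0, 5.0 + length, n_points)
        pts = np.column_stack([np.full(n_points, 10.0 + i * spacing_mm),
                               np.full(n_points, 15.0), z])
        branches.append(Branch(id=i + 1, vessel=["LAD", "LCX", "RCA"][i % 3], points=pts))
    return CoronaryTree(branches=branches, seeds=list(seeds))


@pytest.fixture
def two_parallel_tree():
    return straight_tree(n_branches=2)


def branching_tree():
    """LAD with a D1 child attached mid-vessel, for subtree traversal tests."""
    lad = Branch(
        id=1, vessel="LAD",
        points=np.column_stack([np.full(11, 30.0), np.full(11, 30.0),
                                np.linspace(10.0, 60.0, 11)]),
    )
    d1 = Branch(
        id=2, vessel="LAD", parent=1, attach_index=5,
        points=np.column_stack([np.linspace(30.0, 55.0, 6), np.full(6, 30.0),
                                np.linspace(35.0, 55.0, 6)]),
    )
    lcx = Branch(
        id=3, vessel="LCX",
        points=np.column_stack([np.full(6, 60.0), np.full(6, 60.0),
                                np.linspace(10.0, 60.0, 6)]),
    )
    return CoronaryTree(branches=[lad, d1, lcx], seeds=[])
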
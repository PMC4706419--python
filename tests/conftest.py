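import numpy as np
import pytest

import whiskscape as ws


@pytest.fixture(scope="session")
def default_array():
    return ws.build_default_array()


@pytest.fixture(scope="session")
def coeffs():
    return ws.KinematicCoeffs.default()


@pytest.fixture(scope="session")
def schedule():
    return ws.ProtractionSchedule()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse but bilateral pose grid for fast analysis tests."""
    return ws.PoseGrid(distances=np.arange(0.0, 31.0, 5.0),
                       yaws=np.arange(-90.0, 91.0, 30.0),
                       pitches=np.arange(-90.0, 91.0, 30.0))


@pytest.fixture(scope="session")
def small_table(default_array, coeffs, schedule, small_grid):
    return ws.simulate_grid(default_array, coeffs, schedule, small_grid)


@pytest.fixture(scope="session")
def full_table(default_array, coeffs, schedule):
    """The complete default pose grid (61 x 37 x 37), both sides."""
    import time
    t0 = time.perf_counter()
    table = ws.simulate_grid(default_array, coeffs, schedule, ws.PoseGrid.default())
    table.meta["elapsed_s"] = time.perf_counter() - t0
    return table
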
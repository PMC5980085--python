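"""Shared fixtures: polygons, mode series, and a reusable simulated ensemble."""

import numpy as np
import pytest

from prdcell import prd_sim


def circle_polygon(radius=20.0, center=(0.0, 0.0), n=200):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_ensemble():
    """30-cell, 16-h ensemble at the soft-gel preset (shared across tests)."""
    params = prd_sim.preset("table2_35kPa")
    cfg = prd_sim.SimConfig(duration_h=16.0, n_cells=30, seed=7)
    return prd_sim.simulate_ensemble(params, cfg)
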
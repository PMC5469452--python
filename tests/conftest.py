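import numpy as np
import pandas as pd
import pytest

from cytoprofile.config import ScreenConfig
from cytoprofile.panels import core_panel, full_panel
from cytoprofile.plates import layouts_to_frame
from cytoprofile.profiling import aggregate_wells
from cytoprofile.synthdata import generate_study_design, simulate_screen_cells


@pytest.fixture(scope="session")
def core():
    return core_panel()


@pytest.fixture(scope="session")
def full():
    return full_panel()


@pytest.fixture(scope="session")
def small_screen():
    """A small but complete simulated screen shared across tests.

    2 plants x 3 fractions, 3-dose ladder, triplicate wells, 60 cells/well:
    large enough that replicate averages are stable, small enough to simulate
    in a couple of seconds.
    """
    cfg = ScreenConfig(
        n_plants=2,
        n_fractions_per_plant=3,
        doses=(0.0, 6.25, 25.0),
        n_replicates=3,
        controls_per_plate=16,
    )
    layouts, truth = generate_study_design(cfg, seed=11)
    cells = simulate_screen_cells(layouts, truth, cfg, seed=11, cells_per_well=60)
    layout = layouts_to_frame(layouts)
    return {"config": cfg, "layouts": layouts, "truth": truth, "cells": cells, "layout": layout}


@pytest.fixture(scope="session")
def small_well_means(small_screen, core):
    well_means, qc = aggregate_wells(
        small_screen["cells"], small_screen["layout"], core, min_valid_objects=10
    )
    return well_means, qc


def make_uniform_cells(n, value=5.0, area=50.0, plate="p1", well="A1"):
    """A degenerate cell table where every measurement is constant."""
    from cytoprofile.synthdata import CELL_TABLE_COLUMNS

    data = {c: np.full(n, value) for c in CELL_TABLE_COLUMNS if c.endswith("_mean")}
    data.update(
        plate_id=plate,
        well=well,
        cell_id=np.arange(1, n + 1),
        x=np.linspace(10, 90, n),
        y=np.linspace(10, 90, n),
        nuclear_area=np.full(n, area),
        ring_area=np.full(n, 1.5 * area),
        dna_content=np.full(n, 2 * 500.0),
        true_phase="g0g1",
    )
    return pd.DataFrame(data)
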
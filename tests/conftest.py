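import numpy as np
import pandas as pd
import pytest

from immunobud.synthgen import IntensityModel, TissueSimParams, simulate_cell_table


@pytest.fixture(scope="session")
def sparse_params():
    """Tissue with well-resolvable nuclei: buds dispersed enough that disks
    rarely overlap, so segmentation can recover every cell."""
    return TissueSimParams(
        window_width=400.0,
        window_height=400.0,
        nest_rate=0.0,
        bud_rate=60.0,
        bud_sigma=10.0,
        cd8_intensity=150.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def sparse_realization(sparse_params):
    return simulate_cell_table(sparse_params)


@pytest.fixture(scope="session")
def default_realization():
    params = TissueSimParams(window_width=600.0, window_height=600.0, seed=11)
    return simulate_cell_table(params)


def make_cell_row(**intensities):
    """A single-cell mapping with all channel x compartment keys, zero by
    default."""
    row = {"cell_id": 0, "x": 0.0, "y": 0.0, "nucleus_area": 40.0}
    for ch in ("dapi", "opal520", "opal570", "opal690"):
        for comp in ("nucleus", "cytoplasm", "membrane"):
            row[f"{ch}_{comp}"] = 0.0
    row.update(intensities)
    return row


def cells_frame(rows):
    df = pd.DataFrame(rows)
    df["cell_id"] = np.arange(len(df))
    return df
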
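import numpy as np
import pandas as pd
import pytest

import csma


@pytest.fixture(scope="session")
def small_layout():
    """An 8 x 12 plate with 4 pins and 20 assigned samples + controls."""
    lay = csma.build_layout(8, 12, pitch_um=500, diameter_um=200, n_wells=1, n_pins=4)
    sheet = csma.SampleSheet.from_gene_list([f"G{i:02d}" for i in range(10)], 2)
    return csma.assign_samples(lay, sheet, control_fraction=0.2, seed=3)


@pytest.fixture(scope="session")
def null_spot_cells():
    """One default null spot population (~51 cells) as a measured table."""
    truth = csma.SpotTruth(spot_id=0)
    cells = csma.simulate_spot_cells(truth, seed=42, enforce_spacing=False)
    return csma.truth_to_records(cells, truth)


@pytest.fixture(scope="session")
def big_population():
    """A large (n = 5000) default population for gating tests."""
    truth = csma.SpotTruth(mean_cells=5000, sd_cells=0, spot_diameter_um=4000)
    cells = csma.simulate_spot_cells(truth, seed=7, enforce_spacing=False)
    return cells, csma.truth_to_records(cells, truth)
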
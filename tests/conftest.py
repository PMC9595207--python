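import dataclasses

import pandas as pd
import pytest

from traffiq import design as design_mod
from traffiq.synthetic_data import PlateSimConfig


@pytest.fixture
def noise_free_config():
    """All stochastic terms switched off; pure adipocytes."""
    return PlateSimConfig(
        n_plates=1, wells_per_condition=1, cells_per_well=50,
        adipocyte_fraction=1.0, cell_cv=0.0, plate_gain_sd=0.0,
        plate_offset_sd=0.0, read_noise_sd=0.0, seed=0)


@pytest.fixture
def small_config():
    return PlateSimConfig(n_plates=2, wells_per_condition=2,
                          cells_per_well=200, seed=0)


def single_well_design(insulin_nM, role=design_mod.ROLE_SAMPLE, plate=1,
                       well="A1", **kw):
    row = dict(plate=plate, well=well, role=role, cell_line="3T3-L1",
               insulin_nM=insulin_nM, time_min=float("nan"), inhibitor=None,
               inhibitor_dose=float("nan"), pretreatment=None,
               pretreatment_dose=float("nan"), sirna=None)
    row.update(kw)
    return pd.DataFrame([row], columns=design_mod.DESIGN_COLUMNS)
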
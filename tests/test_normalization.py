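"""Anchored cross-plate normalization and figure-scale summary operations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import single_well_design
from traffiq import design as design_mod
from traffiq.design import ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX, ROLE_SAMPLE
from traffiq.normalization import (fold_over_basal, fold_over_control,
                                   minmax_percent, plate_normalize,
                                   surface_over_total)
from traffiq.synthetic_data import preset, simulate_plate


def _cells_from_values(layout):
    """layout: list of (plate, well, values)."""
    rows = []
    for plate, well, values in layout:
        for i, v in enumerate(values):
            rows.append(dict(plate=plate, well=well, field=1, cell_id=i + 1,
                             glut4_surface=float(v), tfr_surface=float(v),
                             lipid_scatter=0.9))
    return pd.DataFrame(rows)


def _design_from_roles(layout):
    rows = []
    for plate, well, role in layout:
        rows.append(dict(plate=plate, well=well, role=role,
                         cell_line="3T3-L1", insulin_nM=0.0,
                         time_min=np.nan, inhibitor=None,
                         inhibitor_dose=np.nan, pretreatment=None,
                         pretreatment_dose=np.nan, sirna=None))
    return pd.DataFrame(rows, columns=design_mod.DESIGN_COLUMNS)


@pytest.fixture
def two_plate_case():
    # plate 1: med0=100, med100=500; plate 2: med0=120, med100=600
    cells = _cells_from_values([
        (1, "A1", [90, 100, 110]), (1, "A2", [480, 500, 520]),
        (1, "A3", [300]),
        (2, "A1", [110, 120, 130]), (2, "A2", [580, 600, 620]),
    ])
    design = _design_from_roles([
        (1, "A1", ROLE_CONTROL_BASAL), (1, "A2", ROLE_CONTROL_MAX),
        (1, "A3", ROLE_SAMPLE),
        (2, "A1", ROLE_CONTROL_BASAL), (2, "A2", ROLE_CONTROL_MAX),
    ])
    return cells, design


class TestPlateNormalize:
    def test_hand_computed_example(self, two_plate_case):
        # X=300 on plate 1 -> (300-100)*(600-120)/(500-100) + 120 = 360
        cells, design = two_plate_case
        out, anchors = plate_normalize(cells, design, "glut4_surface")
        assert anchors.maxmed0 == 120 and anchors.maxmed100 == 600
        x300 = out.loc[(out["plate"] == 1) & (out["well"] == "A3"),
                       "glut4_surface_norm"].iloc[0]
        assert x300 == pytest.approx(360.0, abs=1e-12)

    def test_anchor_mapping_is_exact(self, two_plate_case):
        cells, design = two_plate_case
        out, anchors = plate_normalize(cells, design, "glut4_surface")
        for plate in (1, 2):
            m = out["plate"] == plate
            basal_wells = design[(design["plate"] == plate)
                                 & (design["role"] == ROLE_CONTROL_BASAL)]["well"]
            max_wells = design[(design["plate"] == plate)
                               & (design["role"] == ROLE_CONTROL_MAX)]["well"]
            med0 = out.loc[m & out["well"].isin(basal_wells),
                           "glut4_surface_norm"].median()
            med100 = out.loc[m & out["well"].isin(max_wells),
                             "glut4_surface_norm"].median()
            assert med0 == pytest.approx(anchors.maxmed0, rel=1e-9)
            assert med100 == pytest.approx(anchors.maxmed100, rel=1e-9)

    def test_single_plate_is_identity(self):
        cells = _cells_from_values([(1, "A1", [90, 100, 110]),
                                    (1, "A2", [480, 500, 520])])
        design = _design_from_roles([(1, "A1", ROLE_CONTROL_BASAL),
                                     (1, "A2", ROLE_CONTROL_MAX)])
        out, _ = plate_normalize(cells, design, "glut4_surface")
        np.testing.assert_allclose(out["glut4_surface_norm"],
                                   out["glut4_surface"])

    def test_idempotence(self, two_plate_case):
        cells, design = two_plate_case
        once, _ = plate_normalize(cells, design, "glut4_surface")
        renamed = once.drop(columns=["glut4_surface", "log2_glut4_surface_norm"])
        renamed = renamed.rename(columns={"glut4_surface_norm": "glut4_surface"})
        twice, _ = plate_normalize(renamed, design, "glut4_surface")
        np.testing.assert_allclose(twice["glut4_surface_norm"],
                                   once["glut4_surface_norm"])

    def test_plate_relabeling_invariance(self, two_plate_case):
        cells, design = two_plate_case
        out1, _ = plate_normalize(cells, design, "glut4_surface")
        swap = {1: 2, 2: 1}
        cells2 = cells.assign(plate=cells["plate"].map(swap))
        design2 = design.assign(plate=design["plate"].map(swap))
        out2, _ = plate_normalize(cells2, design2, "glut4_surface")
        merged = out1.merge(out2, on=["well", "cell_id", "glut4_surface"],
                            suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["glut4_surface_norm_a"],
                                   merged["glut4_surface_norm_b"])

    def test_generator_plates_align_to_machine_precision(self):
        cfg = dataclasses.replace(preset("fig1e", seed=3), n_plates=4,
                                  plate_gain_sd=0.2, plate_offset_sd=10.0)
        design = design_mod.make_dose_design([1.0], n_plates=4)
        cells, _ = simulate_plate(cfg, design)
        out, anchors = plate_normalize(cells, design, "glut4_surface")
        meds0, meds100 = [], []
        for plate, grp in out.merge(design[["plate", "well", "role"]],
                                    on=["plate", "well"]).groupby("plate"):
            meds0.append(grp.loc[grp["role"] == ROLE_CONTROL_BASAL,
                                 "glut4_surface_norm"].median())
            meds100.append(grp.loc[grp["role"] == ROLE_CONTROL_MAX,
                                   "glut4_surface_norm"].median())
        assert np.ptp(meds0) <= 1e-9 * anchors.maxmed100
        assert np.ptp(meds100) <= 1e-9 * anchors.maxmed100
        np.testing.assert_allclose(meds0, anchors.maxmed0, rtol=1e-9)
        np.testing.assert_allclose(meds100, anchors.maxmed100, rtol=1e-9)

    def test_missing_controls_name_the_plate(self, two_plate_case):
        cells, design = two_plate_case
        broken = design[~((design["plate"] == 2)
                          & (design["role"] == ROLE_CONTROL_MAX))]
        with pytest.raises(ValueError, match="plate 2"):
            plate_normalize(cells, broken, "glut4_surface")

    def test_nonresponsive_plate_rejected(self):
        cells = _cells_from_values([(1, "A1", [500, 510]), (1, "A2", [100, 110])])
        design = _design_from_roles([(1, "A1", ROLE_CONTROL_BASAL),
                                     (1, "A2", ROLE_CONTROL_MAX)])
        with pytest.raises(ValueError, match="non-responsive"):
            plate_normalize(cells, design, "glut4_surface")

    def test_nonpositive_values_excluded_from_log2(self, two_plate_case):
        cells, design = two_plate_case
        cells = pd.concat([cells, _cells_from_values([(1, "A3", [-500.0])])],
                          ignore_index=True)
        out, anchors = plate_normalize(cells, design, "glut4_surface")
        assert anchors.n_nonpositive == 1
        assert out["log2_glut4_surface_norm"].isna().sum() == 1


class TestSummaries:
    def test_fold_over_basal(self):
        means = pd.Series({"insulin": 1000.0, "basal": 200.0})
        fob = fold_over_basal(means, basal_mean=200.0)
        assert fob["insulin"] == 5.0 and fob["basal"] == 1.0
        with pytest.raises(ValueError):
            fold_over_basal(means, basal_mean=0.0)

    def test_fob_recovers_generating_fold(self):
        # fig1a preset generates a fivefold basal->100 nM increase
        cfg = dataclasses.replace(preset("fig1a", seed=2), n_plates=1,
                                  cells_per_well=2500, wells_per_condition=2)
        design = design_mod.make_dose_design([], n_plates=1,
                                             wells_per_condition=2)
        cells, truth = simulate_plate(cfg, design)
        merged = cells[truth.is_adipocyte].merge(
            design[["plate", "well", "role"]], on=["plate", "well"])
        means = merged.groupby("role")["glut4_surface"].mean()
        fob = means[ROLE_CONTROL_MAX] / means[ROLE_CONTROL_BASAL]
        assert fob == pytest.approx(5.0, rel=0.05)

    def test_minmax_percent(self):
        assert minmax_percent(400.0, 200.0, 1000.0) == pytest.approx(25.0)
        assert minmax_percent(200.0, 200.0, 1000.0) == 0.0
        assert minmax_percent(1000.0, 200.0, 1000.0) == 100.0
        assert minmax_percent(1200.0, 200.0, 1000.0) > 100.0  # no clamping
        with pytest.raises(ValueError):
            minmax_percent(1.0, 5.0, 5.0)

    def test_surface_over_total(self):
        cells = pd.DataFrame({"glut4_surface": [50.0, 0.0, 10.0],
                              "total_reporter": [200.0, 100.0, 0.0]})
        ratio, n_excluded = surface_over_total(cells)
        assert ratio.iloc[0] == 0.25 and ratio.iloc[1] == 0.0
        assert n_excluded == 1
        # scale invariance
        scaled = cells * 7.3
        ratio2, _ = surface_over_total(scaled)
        np.testing.assert_allclose(ratio2, ratio)
        with pytest.raises(ValueError):
            surface_over_total(cells.drop(columns="total_reporter"))

    def test_fold_over_control(self):
        summary = pd.DataFrame({
            "sirna": ["NT", "kd1", "NT", "kd1"],
            "insulin_nM": [100.0, 100.0, 0.0, 0.0],
            "cell_line": ["wt"] * 4,
            "mean": [100.0, 40.0, 10.0, 10.0],
        })
        out = fold_over_control(summary)
        assert out.loc[1, "foc"] == pytest.approx(0.4)
        assert out.loc[3, "foc"] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="control"):
            fold_over_control(summary[summary["sirna"] != "NT"])
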
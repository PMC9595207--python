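"""Well-condition maps ("designs") for plate experiments.

A design is a pandas DataFrame with one row per well and the columns

    plate, well, role, cell_line, insulin_nM, time_min,
    inhibitor, inhibitor_dose, pretreatment, pretreatment_dose, sirna

``role`` is one of ``control_basal`` (0 nM insulin control anchoring the
bottom of the plate normalization), ``control_max`` (100 nM insulin control
anchoring the top) or ``sample``. ``time_min`` is NaN for steady-state
(20 min stimulation) wells; a finite value marks a kinetic time point.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

DESIGN_COLUMNS = [
    "plate", "well", "role", "cell_line", "insulin_nM", "time_min",
    "inhibitor", "inhibitor_dose", "pretreatment", "pretreatment_dose",
    "sirna",
]

ROLE_CONTROL_BASAL = "control_basal"
ROLE_CONTROL_MAX = "control_max"
ROLE_SAMPLE = "sample"

_ROLES = {ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX, ROLE_SAMPLE}


def _well_names() -> "itertools.count":
    """Infinite well-name generator A1, A2, ..., B1, ... (16x24 layout)."""
    rows = "ABCDEFGHIJKLMNOP"
    return (f"{r}{c}" for r, c in itertools.product(rows, range(1, 25)))


def empty_design() -> pd.DataFrame:
    return pd.DataFrame(columns=DESIGN_COLUMNS)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, role values and well uniqueness; return a copy."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns: {missing}")
    bad = set(design["role"]) - _ROLES
    if bad:
        raise ValueError(f"unknown design roles: {sorted(bad)}")
    dup = design.duplicated(subset=["plate", "well"])
    if dup.any():
        w = design.loc[dup, ["plate", "well"]].iloc[0]
        raise ValueError(f"duplicate well in design: plate {w['plate']} well {w['well']}")
    return design.copy()


def _rows(plate, wells, role, cell_line, insulin, time_min=np.nan,
          inhibitor=None, inhibitor_dose=np.nan,
          pretreatment=None, pretreatment_dose=np.nan, sirna=None):
    return [
        dict(plate=plate, well=w, role=role, cell_line=cell_line,
             insulin_nM=insulin, time_min=time_min, inhibitor=inhibitor,
             inhibitor_dose=inhibitor_dose, pretreatment=pretreatment,
             pretreatment_dose=pretreatment_dose, sirna=sirna)
        for w in wells
    ]


def _take(names, k):
    return [next(names) for _ in range(k)]


def make_dose_design(insulin_doses_nM, n_plates=2, wells_per_condition=2,
                     max_dose_nM=100.0, cell_line="3T3-L1") -> pd.DataFrame:
    """Insulin dose-response layout.

    Every plate carries dedicated control-basal (0 nM) and control-max
    (``max_dose_nM``) wells so the anchored normalization is always defined,
    plus ``wells_per_condition`` sample wells per requested dose.
    """
    recs = []
    for p in range(1, n_plates + 1):
        names = _well_names()
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_BASAL, cell_line, 0.0)
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_MAX, cell_line, max_dose_nM)
        for d in insulin_doses_nM:
            recs += _rows(p, _take(names, wells_per_condition), ROLE_SAMPLE, cell_line, float(d))
    return pd.DataFrame.from_records(recs, columns=DESIGN_COLUMNS)


def make_inhibitor_design(inhibitor, doses, insulin_nM=100.0, n_plates=2,
                          wells_per_condition=2, cell_line="3T3-L1") -> pd.DataFrame:
    """Inhibitor dose-response at a fixed insulin dose (vehicle = dose 0)."""
    recs = []
    for p in range(1, n_plates + 1):
        names = _well_names()
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_BASAL, cell_line, 0.0)
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_MAX, cell_line, 100.0)
        for c in doses:
            recs += _rows(p, _take(names, wells_per_condition), ROLE_SAMPLE, cell_line,
                          insulin_nM, inhibitor=inhibitor, inhibitor_dose=float(c))
    return pd.DataFrame.from_records(recs, columns=DESIGN_COLUMNS)


def make_pretreatment_design(pretreatment, doses, insulin_nM=1.0, n_plates=2,
                             wells_per_condition=2, cell_line="3T3-L1") -> pd.DataFrame:
    """Insulin-resistance model layout: graded chronic pre-treatment followed
    by an acute insulin readout; controls are untreated basal/100 nM wells."""
    recs = []
    for p in range(1, n_plates + 1):
        names = _well_names()
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_BASAL, cell_line, 0.0)
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_MAX, cell_line, 100.0)
        for c in doses:
            recs += _rows(p, _take(names, wells_per_condition), ROLE_SAMPLE, cell_line,
                          insulin_nM, pretreatment=pretreatment,
                          pretreatment_dose=float(c))
    return pd.DataFrame.from_records(recs, columns=DESIGN_COLUMNS)


def make_time_design(times_min, insulin_nM=100.0, n_plates=1,
                     wells_per_condition=2, cell_line="3T3-L1") -> pd.DataFrame:
    """One-phase kinetics layout: one arm of insulin, graded stimulation times.

    Steady-state control wells (basal and 100 nM) are included so the table
    remains normalizable; the kinetic wells carry finite ``time_min``.
    """
    recs = []
    for p in range(1, n_plates + 1):
        names = _well_names()
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_BASAL, cell_line, 0.0)
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_MAX, cell_line, 100.0)
        for t in times_min:
            recs += _rows(p, _take(names, wells_per_condition), ROLE_SAMPLE, cell_line,
                          insulin_nM, time_min=float(t))
    return pd.DataFrame.from_records(recs, columns=DESIGN_COLUMNS)


def make_screen_design(targets, insulin_doses_nM=(0.0, 1.0, 100.0),
                       control_label="NT", n_plates=2, wells_per_condition=2,
                       cell_line="3T3-L1") -> pd.DataFrame:
    """siRNA knockdown screen layout.

    Each plate carries control wells (non-targeting siRNA at 0 and 100 nM,
    doubling as normalization anchors) and every (target x insulin dose)
    combination, including the non-targeting control at every dose.
    """
    recs = []
    all_targets = [control_label] + [t for t in targets if t != control_label]
    for p in range(1, n_plates + 1):
        names = _well_names()
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_BASAL, cell_line,
                      0.0, sirna=control_label)
        recs += _rows(p, _take(names, wells_per_condition), ROLE_CONTROL_MAX, cell_line,
                      100.0, sirna=control_label)
        for t in all_targets:
            for d in insulin_doses_nM:
                recs += _rows(p, _take(names, wells_per_condition), ROLE_SAMPLE, cell_line,
                              float(d), sirna=t)
    return pd.DataFrame.from_records(recs, columns=DESIGN_COLUMNS)
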
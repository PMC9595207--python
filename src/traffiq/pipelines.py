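"""End-to-end workflows: simulate -> gate -> normalize -> summarize -> fit.

These functions wire the library modules together exactly the way the
analysis scripts and the acceptance checks run them, so every headline
quantity (EC50, IC50, half-times, basal fractions, screen FOCs) is computed
through one shared code path.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import design as design_mod
from .design import ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX, ROLE_SAMPLE
from .normalization import minmax_percent, plate_normalize
from .population_stats import crossline_correlation, summarize_screen
from .qc_gating import apply_gate, gate_adipocytes, well_qc
from .response_models import FitResult, fit_hill3, fit_one_phase
from .synthetic_data import PlateSimConfig, preset, simulate_plate, simulate_timecourse

#: default dose/time grids for the figure-style experiments
FIG1E_DOSES_NM = [0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0]
FIG1H_DOSES = {
    "GDC0941": [1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0],
    "MK2206": [10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0],
    "GDC0068": [10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0],
    "GSK23344": [10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0],
}
FIG2_DOSES = {
    "CI": [0.01, 0.03, 0.1, 0.3, 1.0, 10.0],      # nM chronic insulin
    "TNF": [0.01, 0.03, 0.1, 0.3, 1.0, 10.0],     # ng/ml
}
TIMECOURSE_MIN = [0.0, 2.0, 4.0, 6.0, 10.0, 15.0, 25.0, 40.0]


def gate_and_normalize(cells: pd.DataFrame, design: pd.DataFrame,
                       channels: Sequence[str] = ("glut4_surface",),
                       min_cells: int = 50):
    """Standard preprocessing: control-referenced gate, well QC, per-channel
    anchored normalization. Returns (normalized gated cells, anchors dict)."""
    ctrl_wells = design.loc[design["role"].isin(
        [ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX]), ["plate", "well"]]
    reference = cells.merge(ctrl_wells, on=["plate", "well"], how="inner")
    gate = gate_adipocytes(cells, method="otsu", reference=reference)
    qc = well_qc(gate, min_cells=min_cells)
    gated = apply_gate(cells, gate, qc)
    anchors = {}
    for ch in channels:
        gated, anchors[ch] = plate_normalize(gated, design, ch)
    return gated, anchors


def condition_means(cells: pd.DataFrame, design: pd.DataFrame, value_col: str,
                    by: Sequence[str]) -> pd.DataFrame:
    """Well means -> condition mean, SD (over wells), SE and n_wells."""
    meta_cols = list(dict.fromkeys(
        ["plate", "well", "role"] + [c for c in by if c in design.columns]))
    merged = cells.merge(design[meta_cols].drop_duplicates(),
                         on=["plate", "well"], how="inner")
    per_well = (merged.groupby(["plate", "well"] + list(by), dropna=False)
                [value_col].mean().rename("well_mean").reset_index())
    g = per_well.groupby(list(by), dropna=False)["well_mean"]
    out = g.agg(mean="mean", sd="std", n_wells="size").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_wells"])
    return out


# --------------------------------------------------------------------------
# figure-style workflows

def run_insulin_dose_response(seed: int, doses=None, config: Optional[PlateSimConfig] = None
                              ) -> Tuple[FitResult, pd.DataFrame]:
    """fig1e-style pipeline: simulate, gate, normalize, fit stimulation Hill."""
    doses = list(doses if doses is not None else FIG1E_DOSES_NM)
    cfg = config or preset("fig1e", seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    design = design_mod.make_dose_design(doses, n_plates=cfg.n_plates,
                                         wells_per_condition=cfg.wells_per_condition)
    cells, _ = simulate_plate(cfg, design)
    gated, _ = gate_and_normalize(cells, design)
    summ = condition_means(gated, design, "glut4_surface_norm", ["insulin_nM", "role"])
    summ = summ[summ["role"] == ROLE_SAMPLE]
    # dose 0 anchor from the control-basal wells
    basal = condition_means(gated, design, "glut4_surface_norm", ["role"])
    b = basal.loc[basal["role"] == ROLE_CONTROL_BASAL, "mean"].iloc[0]
    x = np.concatenate([[0.0], summ["insulin_nM"].to_numpy()])
    y = np.concatenate([[b], summ["mean"].to_numpy()])
    return fit_hill3(x, y, direction="stimulation"), summ


def run_inhibitor_dose_response(seed: int, inhibitor: str,
                                config: Optional[PlateSimConfig] = None
                                ) -> Tuple[FitResult, pd.DataFrame]:
    """fig1h-style pipeline: inhibitor titration at 100 nM insulin,
    inhibition Hill fit on normalized condition means."""
    cfg = config or preset("fig1h", seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    design = design_mod.make_inhibitor_design(
        inhibitor, FIG1H_DOSES[inhibitor], insulin_nM=100.0,
        n_plates=cfg.n_plates, wells_per_condition=cfg.wells_per_condition)
    cells, _ = simulate_plate(cfg, design)
    gated, _ = gate_and_normalize(cells, design)
    summ = condition_means(gated, design, "glut4_surface_norm",
                           ["inhibitor_dose", "role"])
    summ = summ[summ["role"] == ROLE_SAMPLE]
    maxi = condition_means(gated, design, "glut4_surface_norm", ["role"])
    vehicle = maxi.loc[maxi["role"] == ROLE_CONTROL_MAX, "mean"].iloc[0]
    x = np.concatenate([[0.0], summ["inhibitor_dose"].to_numpy()])
    y = np.concatenate([[vehicle], summ["mean"].to_numpy()])
    return fit_hill3(x, y, direction="inhibition"), summ


def run_resistance_dose_response(seed: int, which: str
                                 ) -> Tuple[FitResult, pd.DataFrame]:
    """fig2c/fig2e-style pipeline: chronic CI or TNF titration, acute 1 nM
    insulin readout, min:max scaling to the control anchors, inhibition fit.

    ``which`` is ``"fig2c"`` (chronic insulin, nM) or ``"fig2e"`` (TNF, ng/ml).
    """
    agent = {"fig2c": "CI", "fig2e": "TNF"}[which]
    cfg = preset(which, seed=seed)
    design = design_mod.make_pretreatment_design(
        agent, FIG2_DOSES[agent], insulin_nM=1.0, n_plates=cfg.n_plates,
        wells_per_condition=cfg.wells_per_condition)
    cells, _ = simulate_plate(cfg, design)
    gated, _ = gate_and_normalize(cells, design)
    ctrl = condition_means(gated, design, "glut4_surface_norm", ["role"])
    basal = ctrl.loc[ctrl["role"] == ROLE_CONTROL_BASAL, "mean"].iloc[0]
    maxi = ctrl.loc[ctrl["role"] == ROLE_CONTROL_MAX, "mean"].iloc[0]
    summ = condition_means(gated, design, "glut4_surface_norm",
                           ["pretreatment_dose", "role"])
    summ = summ[summ["role"] == ROLE_SAMPLE].copy()
    summ["percent"] = minmax_percent(summ["mean"], basal, maxi)
    fit = fit_hill3(summ["pretreatment_dose"], summ["percent"],
                    direction="inhibition")
    return fit, summ


def run_kinetics(seed: int, insulin_nM: float, halftime: float,
                 config: Optional[PlateSimConfig] = None,
                 channel: str = "glut4_surface",
                 times=None) -> Tuple[FitResult, pd.DataFrame]:
    """Time-course pipeline: simulate one-phase translocation, fit t1/2
    from gated per-time condition means (affine-invariant, so raw means)."""
    times = list(times if times is not None else TIMECOURSE_MIN)
    cfg = config or preset("fig1g", seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    cells, _ = simulate_timecourse(cfg, times, halftime, insulin_nM=insulin_nM)
    design = design_mod.make_time_design(times, insulin_nM=insulin_nM,
                                         n_plates=cfg.n_plates,
                                         wells_per_condition=cfg.wells_per_condition)
    ctrl_wells = design.loc[design["role"].isin(
        [ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX]), ["plate", "well"]]
    reference = cells.merge(ctrl_wells, on=["plate", "well"], how="inner")
    gate = gate_adipocytes(cells, method="otsu", reference=reference)
    gated = apply_gate(cells, gate, well_qc(gate))
    summ = condition_means(gated, design, channel, ["time_min", "role"])
    summ = summ[summ["role"] == ROLE_SAMPLE]
    fit = fit_one_phase(summ["time_min"], summ["mean"])
    return fit, summ


def run_tfr_kinetics(seed: int, times=None) -> Tuple[FitResult, pd.DataFrame]:
    """fig4d TfR arm: 100 nM insulin time course of the TfR channel."""
    cfg = preset("fig4d", seed=seed)
    # the GLUT4 half-time ships with the preset; the TfR channel uses
    # cfg.tfr_halftime_min internally
    return run_kinetics(seed, insulin_nM=100.0,
                        halftime=cfg.glut4_halftime(100.0), config=cfg,
                        channel="tfr_surface", times=times)


def run_basal_fraction(seed: int, channel: str) -> Dict[str, float]:
    """fig4d basal occupancy: 100 * basal / maximal condition mean with a
    propagated Monte-Carlo standard error, from gated raw intensities."""
    cfg = preset("fig4d", seed=seed)
    design = design_mod.make_dose_design([], n_plates=cfg.n_plates,
                                         wells_per_condition=4)
    cells, _ = simulate_plate(cfg, design)
    gate = gate_adipocytes(cells)
    gated = apply_gate(cells, gate, well_qc(gate))
    merged = gated.merge(design[["plate", "well", "role"]], on=["plate", "well"])
    stats = {}
    for role in (ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX):
        vals = merged.loc[merged["role"] == role, channel]
        stats[role] = (vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals)))
    (mb, seb), (mm, sem) = stats[ROLE_CONTROL_BASAL], stats[ROLE_CONTROL_MAX]
    pct = 100.0 * mb / mm
    se = pct * np.hypot(seb / mb, sem / mm)
    return {"percent": float(pct), "se": float(se),
            "basal_mean": float(mb), "max_mean": float(mm),
            "n_cells": int(len(merged))}


def run_screen(seed: int, config: Optional[PlateSimConfig] = None,
               insulin_doses=(0.0, 1.0, 100.0)):
    """fig6-style knockdown screen: simulate, preprocess, summarize per
    (target x dose x readout) with FOC against the non-targeting control."""
    cfg = config or preset("fig6_screen", seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    targets = sorted(cfg.knockdown_effects)
    design = design_mod.make_screen_design(
        targets, insulin_doses_nM=insulin_doses, control_label=cfg.control_sirna,
        n_plates=cfg.n_plates, wells_per_condition=cfg.wells_per_condition)
    cells, truth = simulate_plate(cfg, design)
    gated, _ = gate_and_normalize(cells, design,
                                  channels=("glut4_surface", "tfr_surface"))
    summary = summarize_screen(
        gated, design,
        readouts=("glut4", "tfr", "nuclei_per_field", "droplet_count",
                  "droplet_area_mean"),
        control_label=cfg.control_sirna)
    return summary, truth


def run_crossline_slope(seed: int, shrink: float = 0.5,
                        n_targets: int = 12) -> Dict[str, float]:
    """Paired-screen regression: line B's knockdown effects are line A's
    shrunk toward 1 by ``shrink``; returns the fitted slope etc."""
    rng = np.random.default_rng(seed)
    effects_a = {f"T{i:02d}": {"glut4_surface": float(e)}
                 for i, e in enumerate(rng.uniform(0.2, 1.4, n_targets))}
    effects_b = {t: {"glut4_surface": 1.0 + shrink * (v["glut4_surface"] - 1.0)}
                 for t, v in effects_a.items()}
    focs = {}
    for line, effects, s in (("A", effects_a, seed + 101),
                             ("B", effects_b, seed + 202)):
        cfg = dataclasses.replace(preset("fig6_screen", seed=s),
                                  knockdown_effects=effects, seed=s)
        summary, _ = run_screen(s, config=cfg, insulin_doses=(100.0,))
        sub = summary[(summary["readout"] == "glut4")
                      & (summary["insulin_nM"] == 100.0)
                      & (summary["sirna"] != cfg.control_sirna)]
        focs[line] = sub.set_index("sirna")["foc"]
    res = crossline_correlation(focs["A"], focs["B"])
    return {"slope": res.slope, "intercept": res.intercept, "r2": res.r2,
            "p_value": res.p_value, "n": res.n, "true_shrink": shrink}
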
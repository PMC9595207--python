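"""Seeded generators for synthetic cell tables and AP-MS protein-groups tables.

The plate generator emulates a high-content surface-staining assay in
differentiated 3T3-L1 adipocytes: per-cell surface GLUT4 and TfR intensities
are drawn lognormally around well-level true means determined by a
Hill-type insulin response, optional inhibitor / chronic-pretreatment
suppression, optional siRNA knockdown effects, and one-phase association
kinetics. Plates carry a multiplicative gain and a small additive offset;
a fibroblast subpopulation has a low lipid-scatter score and no insulin
response. The IP-MS generator emulates a bait-vs-IgG label-free proteomics
matrix with intensity-dependent (missing-not-at-random) dropout.

Every generator returns its ground truth alongside the data, and identical
(config, seed) pairs reproduce outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import design as design_mod
from .design import DESIGN_COLUMNS, validate_design

CELL_COLUMNS = [
    "plate", "well", "field", "cell_id", "glut4_surface", "tfr_surface",
    "lipid_scatter", "total_reporter", "droplet_count", "droplet_area_total",
]


# --------------------------------------------------------------------------
# configs

@dataclass
class PlateSimConfig:
    """Generating parameters for one plate experiment.

    Intensities are in arbitrary fluorescence units (AFU); doses in nM
    (TNF pretreatment doses in ng/ml); times in minutes.
    """

    n_plates: int = 2
    wells_per_condition: int = 2
    cells_per_well: int = 500          # mean of the per-well Poisson draw
    adipocyte_fraction: float = 0.9    # >=90% of cells differentiate
    basal_mean: float = 200.0          # true adipocyte surface GLUT4, 0 nM insulin
    insulin_max_mean: float = 1000.0   # true surface GLUT4 at saturating insulin
    hill_ec50: float = 0.86            # nM, insulin dose-response
    cell_cv: float = 0.35              # CV of the lognormal per-cell noise
    plate_gain_sd: float = 0.10        # SD of the per-plate multiplicative gain
    plate_offset_sd: float = 1.0       # AFU, SD of the per-plate additive offset
    read_noise_sd: float = 1.0         # AFU, additive half-normal read noise
    fibroblast_scatter_mean: float = 0.2
    adipocyte_scatter_mean: float = 0.9
    scatter_sd: float = 0.08
    # second channel: transferrin receptor (higher basal occupancy, faster)
    tfr_basal_mean: float = 350.0
    tfr_max_mean: float = 1000.0
    tfr_halftime_min: float = 3.0
    # kinetics of the GLUT4 channel, per insulin dose (nM -> t1/2 in min)
    glut4_halftime_by_insulin: Dict[float, float] = field(
        default_factory=lambda: {100.0: 7.5, 1.0: 9.5})
    # named perturbations the response model understands
    inhibitor_ic50s: Dict[str, float] = field(
        default_factory=lambda: {"GDC0941": 8.0, "MK2206": 183.0,
                                 "GDC0068": 121.0, "GSK23344": 289.0})
    pretreatment_ic50s: Dict[str, float] = field(
        default_factory=lambda: {"CI": 0.17, "TNF": 0.18})
    # siRNA target -> per-readout multiplier on the well true mean
    knockdown_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    control_sirna: str = "NT"
    # bookkeeping channels
    fields_per_well: int = 4
    total_reporter_mean: float = 5000.0
    droplet_count_mean: float = 8.0
    droplet_area_mean: float = 12.0    # area units per droplet
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_plates", "wells_per_condition", "cells_per_well",
                     "fields_per_well"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.adipocyte_fraction <= 1.0:
            raise ValueError("adipocyte_fraction must lie in [0, 1]")
        if self.hill_ec50 <= 0:
            raise ValueError("hill_ec50 must be > 0")
        if self.cell_cv < 0:
            raise ValueError("cell_cv must be >= 0")
        if self.insulin_max_mean <= self.basal_mean:
            raise ValueError("insulin_max_mean must exceed basal_mean")

    def glut4_halftime(self, insulin_nM: float) -> float:
        try:
            return self.glut4_halftime_by_insulin[float(insulin_nM)]
        except KeyError:
            raise KeyError(
                f"no GLUT4 half-time registered for insulin dose {insulin_nM} nM")


@dataclass
class IpmsSimConfig:
    """Generating parameters for a bait-vs-IgG AP-MS LFQ matrix (log2 scale).

    Replicate noise is intensity-dependent (low-intensity proteins quantify
    noisily, as in real LFQ data); missingness is logistic in true log2
    intensity with probability ``logistic((dropout_midpoint - x) / dropout_slope)``.
    """

    n_proteins: int = 1000
    n_replicates: int = 3              # per (bait/IgG x basal/insulin)
    background_log2_mean: float = 25.5
    background_log2_sd: float = 1.8
    enriched_fraction: float = 0.08    # true bait interactors
    enrichment_log2_effect: float = 4.0
    regulated_fraction: float = 0.25   # of the enriched set, insulin-regulated
    insulin_delta_log2: float = 2.5    # extra bait enrichment under insulin
    rep_noise_sd_high: float = 0.30    # replicate SD, abundant proteins
    rep_noise_sd_low: float = 0.75     # replicate SD near the detection limit
    noise_midpoint_log2: float = 27.5  # logistic transition between the two
    dropout_midpoint: float = 22.0
    dropout_slope: float = 1.0
    flag_fraction: float = 0.02        # each of Reverse / contaminant / site-only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if not 0.0 <= self.regulated_fraction <= 1.0:
            raise ValueError("regulated_fraction must lie in [0, 1]")
        if self.dropout_slope <= 0:
            raise ValueError("dropout_slope must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition for imputation")


@dataclass
class SimTruth:
    """Ground truth emitted next to every generated dataset."""

    wells: Optional[pd.DataFrame] = None       # plate, well, per-channel true mean
    plates: Optional[pd.DataFrame] = None      # plate, gain, offset
    is_adipocyte: Optional[np.ndarray] = None  # per cell-table row
    # proteomics truth
    true_log2: Optional[pd.DataFrame] = None   # protein x sample, pre-dropout
    enriched_proteins: Optional[List[str]] = None
    regulated_proteins: Optional[List[str]] = None


# --------------------------------------------------------------------------
# response model

def _hill_stim(dose: float, ec50: float) -> float:
    return 0.0 if dose <= 0 else dose / (ec50 + dose)


def _hill_inhib(dose: float, ic50: float) -> float:
    return ic50 / (ic50 + dose)


def _one_phase(t: float, halftime: float) -> float:
    return 1.0 - 2.0 ** (-t / halftime)


def _lookup(table: Dict[str, float], name, dose, well, kind) -> float:
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return 1.0
    if name not in table:
        raise ValueError(
            f"well {well}: unknown {kind} {name!r}; known: {sorted(table)}")
    return _hill_inhib(float(dose), table[name])


def well_true_mean(config: PlateSimConfig, condition: pd.Series, channel: str) -> float:
    """True adipocyte mean intensity for one well and channel.

    The model is ``kd * (basal + (max - basal) * stim * inhib * pretreat * time)``
    where ``stim`` is the Hill insulin response, ``inhib``/``pretreat`` are
    inhibitory Hill factors for named compounds, and ``time`` is the one-phase
    association factor (1 at steady state).
    """
    if channel == "glut4_surface":
        lo, hi = config.basal_mean, config.insulin_max_mean
    elif channel == "tfr_surface":
        lo, hi = config.tfr_basal_mean, config.tfr_max_mean
    else:
        raise ValueError(f"unknown intensity channel {channel!r}")

    well = f"plate {condition['plate']} well {condition['well']}"
    dose = float(condition["insulin_nM"])
    stim = _hill_stim(dose, config.hill_ec50)
    inhib = _lookup(config.inhibitor_ic50s, condition.get("inhibitor"),
                    condition.get("inhibitor_dose", np.nan), well, "inhibitor")
    pre = _lookup(config.pretreatment_ic50s, condition.get("pretreatment"),
                  condition.get("pretreatment_dose", np.nan), well, "pretreatment")

    t = condition.get("time_min", np.nan)
    if t is not None and np.isfinite(t):
        halftime = (config.tfr_halftime_min if channel == "tfr_surface"
                    else config.glut4_halftime(dose))
        tf = _one_phase(float(t), halftime)
    else:
        tf = 1.0

    sirna = condition.get("sirna")
    kd = 1.0
    if sirna is not None and not (isinstance(sirna, float) and np.isnan(sirna)):
        if sirna != config.control_sirna and sirna not in config.knockdown_effects:
            raise ValueError(f"well {well}: unknown siRNA target {sirna!r}")
        kd = config.knockdown_effects.get(sirna, {}).get(channel, 1.0)

    return kd * (lo + (hi - lo) * stim * inhib * pre * tf)


# --------------------------------------------------------------------------
# plate generator

def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_plate(config: PlateSimConfig, design: pd.DataFrame):
    """Generate a per-cell measurement table for the given well map.

    Returns ``(cells, truth)`` where ``cells`` follows the standard cell-table
    schema and ``truth`` records per-well true means, per-plate gain/offset
    and the per-cell adipocyte label. Fibroblasts draw from the basal
    distribution regardless of any stimulus and from the low-scatter mode.
    """
    design = validate_design(design)
    rng = np.random.default_rng(config.seed)

    plates = sorted(design["plate"].unique())
    gains = 1.0 + rng.normal(0.0, config.plate_gain_sd, size=len(plates))
    offsets = rng.normal(0.0, config.plate_offset_sd, size=len(plates))
    plate_fx = {p: (g, o) for p, g, o in zip(plates, gains, offsets)}

    well_truth = []
    frames = []
    labels = []
    for _, cond in design.iterrows():
        mean_g4 = well_true_mean(config, cond, "glut4_surface")
        mean_tfr = well_true_mean(config, cond, "tfr_surface")
        gain, offset = plate_fx[cond["plate"]]
        n = max(1, rng.poisson(config.cells_per_well))
        adipo = rng.random(n) < config.adipocyte_fraction

        kd = 1.0
        sirna = cond.get("sirna")
        if isinstance(sirna, str):
            kd_drop = config.knockdown_effects.get(sirna, {})
            kd = kd_drop.get("droplet_count", 1.0)

        g4 = np.where(adipo, mean_g4, config.basal_mean) * _lognormal_factor(rng, config.cell_cv, n)
        tfr = np.where(adipo, mean_tfr, config.tfr_basal_mean) * _lognormal_factor(rng, config.cell_cv, n)
        g4 = gain * g4 + offset + np.abs(rng.normal(0, config.read_noise_sd, n))
        tfr = gain * tfr + offset + np.abs(rng.normal(0, config.read_noise_sd, n))

        scatter_mu = np.where(adipo, config.adipocyte_scatter_mean,
                              config.fibroblast_scatter_mean)
        scatter = np.clip(rng.normal(scatter_mu, config.scatter_sd), 0.0, None)

        total = config.total_reporter_mean * _lognormal_factor(rng, config.cell_cv, n)
        drop_n = np.where(adipo, rng.poisson(config.droplet_count_mean * kd, n), 0)
        area = drop_n * config.droplet_area_mean * _lognormal_factor(rng, 0.2, n)

        frames.append(pd.DataFrame({
            "plate": cond["plate"], "well": cond["well"],
            "field": rng.integers(1, config.fields_per_well + 1, n),
            "cell_id": np.arange(1, n + 1),
            "glut4_surface": g4, "tfr_surface": tfr, "lipid_scatter": scatter,
            "total_reporter": total, "droplet_count": drop_n,
            "droplet_area_total": area,
        }))
        labels.append(adipo)
        well_truth.append(dict(plate=cond["plate"], well=cond["well"],
                               glut4_mean=mean_g4, tfr_mean=mean_tfr))

    cells = pd.concat(frames, ignore_index=True)[CELL_COLUMNS]
    truth = SimTruth(
        wells=pd.DataFrame(well_truth),
        plates=pd.DataFrame({"plate": plates, "gain": gains, "offset": offsets}),
        is_adipocyte=np.concatenate(labels),
    )
    return cells, truth


def simulate_timecourse(config: PlateSimConfig, times: Sequence[float],
                        halftime: float, insulin_nM: float = 100.0):
    """One-phase association time course of the GLUT4 channel at one insulin dose.

    The well true mean follows S(t) = S0 + (Splateau - S0) * (1 - 2^(-t/t1/2)).
    """
    if halftime <= 0:
        raise ValueError("halftime must be > 0")
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise ValueError("times must be >= 0")
    cfg = dataclasses.replace(
        config, glut4_halftime_by_insulin={float(insulin_nM): float(halftime)})
    design = design_mod.make_time_design(
        times, insulin_nM=insulin_nM, n_plates=cfg.n_plates,
        wells_per_condition=cfg.wells_per_condition)
    return simulate_plate(cfg, design)


# --------------------------------------------------------------------------
# IP-MS generator

def ipms_sample_names(n_replicates: int):
    """Standard sample layout: (bait|IgG) x (basal|insulin) x replicate."""
    names, rows = [], []
    for group in ("bait", "IgG"):
        for condition in ("basal", "insulin"):
            for r in range(1, n_replicates + 1):
                s = f"{group}_{condition}_{r}"
                names.append(s)
                rows.append(dict(sample=s, group=group, condition=condition,
                                 replicate=r))
    return names, pd.DataFrame(rows)


def dropout_probability(log2_intensity: np.ndarray, midpoint: float,
                        slope: float) -> np.ndarray:
    """Logistic MNAR missingness probability in log2 intensity."""
    z = (midpoint - np.asarray(log2_intensity, dtype=float)) / slope
    return 1.0 / (1.0 + np.exp(-z))


def simulate_ipms(config: IpmsSimConfig):
    """Generate a MaxQuant-style protein-groups table plus ground truth.

    Output intensities are linear-scale LFQ values (0 = missing), with flag
    columns Reverse / Potential contaminant / Only identified by site set on
    a small decoy fraction of extra rows so that downstream filtering is
    exercised. Truth carries the complete pre-dropout log2 matrix and the
    identities of the enriched and insulin-regulated proteins.
    """
    rng = np.random.default_rng(config.seed)
    samples, sample_design = ipms_sample_names(config.n_replicates)

    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    base = rng.normal(config.background_log2_mean, config.background_log2_sd, n)

    n_enriched = int(round(config.enriched_fraction * n))
    enriched = np.zeros(n, dtype=bool)
    enriched[rng.choice(n, size=n_enriched, replace=False)] = True
    enr_idx = np.flatnonzero(enriched)
    n_reg = int(round(config.regulated_fraction * n_enriched))
    regulated = np.zeros(n, dtype=bool)
    if n_reg and config.enrichment_log2_effect != 0:
        regulated[rng.choice(enr_idx, size=n_reg, replace=False)] = True
    if config.enrichment_log2_effect == 0:
        enriched[:] = False
        regulated[:] = False

    true_log2 = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        grp, cond, _ = s.split("_")
        mu = base.copy()
        if grp == "bait":
            mu = mu + np.where(enriched, config.enrichment_log2_effect, 0.0)
            if cond == "insulin":
                mu = mu + np.where(regulated, config.insulin_delta_log2, 0.0)
        # intensity-dependent replicate noise: noisy near the detection limit
        w = 1.0 / (1.0 + np.exp(mu - config.noise_midpoint_log2))
        sd = config.rep_noise_sd_high + (config.rep_noise_sd_low
                                         - config.rep_noise_sd_high) * w
        true_log2[:, j] = mu + rng.normal(0.0, 1.0, n) * sd

    p_miss = dropout_probability(true_log2, config.dropout_midpoint,
                                 config.dropout_slope)
    missing = rng.random(true_log2.shape) < p_miss
    observed = np.where(missing, 0.0, 2.0 ** true_log2)

    table = pd.DataFrame({"Protein IDs": ids})
    for j, s in enumerate(samples):
        table[f"LFQ intensity {s}"] = observed[:, j]
    # QC flags exercise the decoy/contaminant filters; they mark background
    # rows only, so the planted interactor truth stays recoverable
    for col in ("Reverse", "Potential contaminant", "Only identified by site"):
        flags = (rng.random(n) < config.flag_fraction) & ~enriched
        table[col] = np.where(flags, "+", "")

    truth = SimTruth(
        true_log2=pd.DataFrame(true_log2, index=ids, columns=samples),
        enriched_proteins=[ids[i] for i in np.flatnonzero(enriched)],
        regulated_proteins=[ids[i] for i in np.flatnonzero(regulated)],
    )
    return (table, sample_design), truth


# --------------------------------------------------------------------------
# presets

def _fig1e(seed):  # insulin dose-response, bicarbonate buffer
    return PlateSimConfig(hill_ec50=0.86, seed=seed)


def _fig1a(seed):  # basal vs 100 nM: fivefold fold-over-basal
    return PlateSimConfig(basal_mean=200.0, insulin_max_mean=1000.0, seed=seed)


def _fig1g(seed):  # GLUT4 translocation kinetics at 100 and 1 nM insulin
    return PlateSimConfig(
        glut4_halftime_by_insulin={100.0: 7.5, 1.0: 9.5}, seed=seed)


def _fig1h(seed):  # PI3K/Akt inhibitor suppression at 100 nM insulin
    return PlateSimConfig(
        inhibitor_ic50s={"GDC0941": 8.0, "MK2206": 183.0,
                         "GDC0068": 121.0, "GSK23344": 289.0}, seed=seed)


def _fig2c(seed):  # chronic-insulin resistance model, 1 nM acute readout
    return PlateSimConfig(pretreatment_ic50s={"CI": 0.17}, seed=seed)


def _fig2e(seed):  # TNF resistance model (doses in ng/ml), 1 nM acute readout
    return PlateSimConfig(pretreatment_ic50s={"TNF": 0.18}, seed=seed)


def _fig4d(seed):  # dual GLUT4/TfR readout: basal occupancy and kinetics
    return PlateSimConfig(
        n_plates=1,
        basal_mean=65.0, insulin_max_mean=1000.0,     # GLUT4 basal = 6.5% of max
        tfr_basal_mean=350.0, tfr_max_mean=1000.0,    # TfR basal = 35% of max
        tfr_halftime_min=3.0,
        glut4_halftime_by_insulin={100.0: 9.0},
        seed=seed)


def _fig6_screen(seed):  # knockdown screen with graded trafficking effects
    return PlateSimConfig(
        knockdown_effects={
            "Rab10": {"glut4_surface": 0.4},
            "Kif13A": {"glut4_surface": 0.6, "tfr_surface": 0.8},
            "Tfrc": {"tfr_surface": 0.2},
            "Lipo1": {"droplet_count": 0.5},
        },
        seed=seed)


def _ipms_default(seed):
    return IpmsSimConfig(seed=seed)


_PRESETS = {
    "fig1a": _fig1a, "fig1e": _fig1e, "fig1g": _fig1g, "fig1h": _fig1h,
    "fig2c": _fig2c, "fig2e": _fig2e, "fig4d": _fig4d,
    "fig6_screen": _fig6_screen, "ipms_default": _ipms_default,
}

#: provenance of preset parameters (figure panel -> parameter -> value)
PRESET_CITATIONS = {
    "fig1a": {"fold over basal (100 nM / basal)": 5.0},
    "fig1e": {"insulin EC50 (nM)": 0.86},
    "fig1g": {"GLUT4 t1/2 at 100 nM insulin (min)": 7.5,
              "GLUT4 t1/2 at 1 nM insulin (min)": 9.5},
    "fig1h": {"GDC0941 IC50 (nM)": 8.0, "MK2206 IC50 (nM)": 183.0,
              "GDC0068 IC50 (nM)": 121.0, "GSK23344 IC50 (nM)": 289.0},
    "fig2c": {"chronic-insulin IC50 at 1 nM insulin (nM)": 0.17},
    "fig2e": {"TNF IC50 at 1 nM insulin (ng/ml)": 0.18},
    "fig4d": {"TfR basal (% of max)": 35.0, "GLUT4 basal (% of max)": 6.5,
              "TfR t1/2 (min)": 3.0, "GLUT4 t1/2 (min)": 9.0},
    "fig6_screen": {"example GLUT4 knockdown effect (x control)": 0.4},
    "ipms_default": {"biological replicates": 3},
}


def preset(name: str, seed: int = 0):
    """Return the named, fully parameterized simulation config."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return factory(seed)
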
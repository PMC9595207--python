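"""Single-cell distribution analysis and knockdown-screen summarization.

Covers the kernel-density views of single-cell normalized intensities,
a median-based population shift metric (0 = basal-like, 1 = fully
insulin-stimulated), per-readout screen summaries with fold-over-control,
lipid-droplet summaries, and the cross-cell-line regression of knockdown
effects. Wells, not cells, are the unit of replication for screen SDs.

Inference across screen targets uses two-sided Welch tests with
Benjamini-Hochberg correction per readout — a documented, simpler
substitute for the repeated-measures ANOVA machinery of graphing software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import fold_over_control

SCREEN_READOUTS = {
    "glut4": "log-free mean of the normalized surface-GLUT4 channel",
    "tfr": "mean of the normalized surface-TfR channel",
    "nuclei_per_field": "nuclei per field of view",
    "droplet_count": "per-cell lipid droplet count",
    "droplet_area_mean": "mean area per droplet",
}


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    @property
    def peak(self) -> float:
        """Grid location of the global density maximum."""
        return float(self.grid[int(np.argmax(self.density))])

    def local_maxima(self) -> np.ndarray:
        d = self.density
        idx = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])) + 1
        return self.grid[idx]

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def density_estimate(values: Sequence[float], bandwidth: Optional[float] = None,
                     grid: Optional[np.ndarray] = None,
                     gridsize: int = 512) -> DensityCurve:
    """Gaussian-kernel density of single-cell (log2) intensities.

    Bandwidth defaults to Silverman's rule. The evaluation grid extends
    4 bandwidths beyond the data range so the curve integrates to ~1;
    pass a shared ``grid`` to make curves across conditions comparable.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 finite values for a density ({len(x)} given)")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: density undefined")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / x.std(ddof=1))
    bw = float(kde.factor * x.std(ddof=1))
    if grid is None:
        grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, gridsize)
    return DensityCurve(grid=np.asarray(grid, dtype=float),
                        density=kde(grid), bandwidth=bw, n=len(x))


def shift_metric(condition: Sequence[float], basal_ctrl: Sequence[float],
                 max_ctrl: Sequence[float]) -> float:
    """Median-based position of a population between the control anchors.

    0 means fully basal-like, 1 fully insulin-stimulated; intermediate
    values quantify the leftward shift of insulin-resistant populations.
    Invariant under any common affine transform of the three populations.
    """
    pops = [np.asarray(p, dtype=float) for p in (condition, basal_ctrl, max_ctrl)]
    if any(len(p) == 0 for p in pops):
        raise ValueError("all three populations must be nonempty")
    med_c, med_b, med_m = (float(np.median(p)) for p in pops)
    if med_m == med_b:
        raise ValueError("degenerate controls: basal and max medians equal")
    return (med_c - med_b) / (med_m - med_b)


def _well_aggregates(cells: pd.DataFrame, readouts) -> pd.DataFrame:
    """Per-well values for each requested readout; unknown/missing skipped."""
    keys = ["plate", "well"]
    per_well = cells[keys].drop_duplicates().reset_index(drop=True)
    channel_cols = {"glut4": "glut4_surface_norm", "tfr": "tfr_surface_norm"}
    for r in readouts:
        if r in channel_cols:
            col = channel_cols[r]
            if col not in cells.columns:  # fall back to the raw channel
                col = col.removesuffix("_norm")
            if col not in cells.columns:
                warnings.warn(f"readout {r!r}: column {col!r} absent, skipped")
                continue
            agg = cells.groupby(keys)[col].mean().rename(r).reset_index()
        elif r == "nuclei_per_field":
            agg = (cells.groupby(keys + ["field"]).size().rename("n")
                   .reset_index().groupby(keys)["n"].mean().rename(r).reset_index())
        elif r == "droplet_count":
            if "droplet_count" not in cells.columns:
                warnings.warn("readout 'droplet_count': column absent, skipped")
                continue
            agg = cells.groupby(keys)["droplet_count"].mean().rename(r).reset_index()
        elif r == "droplet_area_mean":
            if not {"droplet_count", "droplet_area_total"} <= set(cells.columns):
                warnings.warn("readout 'droplet_area_mean': columns absent, skipped")
                continue
            g = cells.groupby(keys)[["droplet_count", "droplet_area_total"]].sum()
            agg = ((g["droplet_area_total"] / g["droplet_count"].replace(0, np.nan))
                   .rename(r).reset_index())
        else:
            warnings.warn(f"unknown readout {r!r} skipped")
            continue
        per_well = per_well.merge(agg, on=keys, how="left")
    return per_well


def summarize_screen(cells: pd.DataFrame, design: pd.DataFrame,
                     readouts: Sequence[str] = ("glut4", "tfr"),
                     control_label: str = "NT",
                     welch_tests: bool = True) -> pd.DataFrame:
    """Knockdown-screen summary: per-condition mean +/- SD, n wells and FOC.

    ``cells`` should be gated (and normalized for the intensity readouts);
    conditions are (siRNA target x insulin dose x cell line), wells are the
    replication unit, and FOC is relative to the non-targeting control in
    the same insulin/cell-line stratum. ``role == sample`` wells only.
    """
    per_well = _well_aggregates(cells, readouts)
    meta = design[["plate", "well", "role", "sirna", "insulin_nM", "cell_line"]]
    per_well = per_well.merge(meta, on=["plate", "well"], how="inner")
    per_well = per_well[per_well["role"] == "sample"]
    present = [r for r in readouts if r in per_well.columns]

    rows = []
    group_cols = ["sirna", "insulin_nM", "cell_line"]
    for keys_, grp in per_well.groupby(group_cols, dropna=False):
        for r in present:
            vals = grp[r].dropna()
            rows.append(dict(zip(group_cols, keys_),
                             readout=r, mean=vals.mean(),
                             sd=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                             n_wells=len(vals)))
    summary = pd.DataFrame(rows)
    if summary.empty:
        raise ValueError("no sample wells after joining design")

    out = []
    for r, grp in summary.groupby("readout"):
        foc = fold_over_control(grp, value_col="mean", condition_col="sirna",
                                control_label=control_label)
        out.append(foc)
    summary = pd.concat(out, ignore_index=True)

    if welch_tests:
        summary = _attach_welch_bh(summary, per_well, present, control_label,
                                   group_cols)
    return summary


def _attach_welch_bh(summary, per_well, readouts, control_label, group_cols):
    pvals = np.full(len(summary), np.nan)
    for i, row in summary.iterrows():
        if row["sirna"] == control_label:
            continue
        stratum = ((per_well["insulin_nM"] == row["insulin_nM"])
                   & (per_well["cell_line"] == row["cell_line"]))
        a = per_well.loc[stratum & (per_well["sirna"] == row["sirna"]),
                         row["readout"]].dropna()
        b = per_well.loc[stratum & (per_well["sirna"] == control_label),
                         row["readout"]].dropna()
        if len(a) >= 2 and len(b) >= 2:
            pvals[i] = stats.ttest_ind(a, b, equal_var=False).pvalue
    summary = summary.copy()
    summary["p_welch"] = pvals
    summary["p_adj"] = np.nan
    for r in readouts:  # BH across targets within each readout
        m = summary["readout"].eq(r) & summary["p_welch"].notna()
        if m.any():
            summary.loc[m, "p_adj"] = multipletests(
                summary.loc[m, "p_welch"], method="fdr_bh")[1]
    return summary


def crossline_correlation(foc_a: pd.Series, foc_b: pd.Series) -> CorrelationResult:
    """Simple linear regression of per-target FOC in line B on line A.

    Both series are indexed by knockdown target; only shared targets enter.
    """
    shared = foc_a.index.intersection(foc_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared targets ({len(shared)} found)")
    a = foc_a.loc[shared].to_numpy(dtype=float)
    b = foc_b.loc[shared].to_numpy(dtype=float)
    res = stats.linregress(a, b)
    r = res.rvalue if np.isfinite(res.rvalue) else 0.0  # constant response
    return CorrelationResult(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r2=float(r ** 2),
                             p_value=float(res.pvalue), n=len(shared))


def lipid_summaries(cells: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-condition lipid-droplet load: well droplet totals, per-cell mean
    counts and mean droplet area, aggregated to condition mean +/- SD."""
    need = {"droplet_count", "droplet_area_total"}
    if not need <= set(cells.columns):
        raise ValueError(f"droplet columns missing: {sorted(need - set(cells.columns))}")
    if cells["droplet_count"].isna().all():
        raise ValueError("droplet columns are empty")
    keys = ["plate", "well"]
    g = cells.groupby(keys)
    per_well = pd.DataFrame({
        "droplet_total": g["droplet_count"].sum(),
        "droplet_count_mean": g["droplet_count"].mean(),
        "droplet_area_mean": (g["droplet_area_total"].sum()
                              / g["droplet_count"].sum().replace(0, np.nan)),
    }).reset_index()
    meta = design[["plate", "well", "sirna", "insulin_nM", "cell_line"]]
    per_well = per_well.merge(meta, on=keys, how="inner")
    rows = []
    for keys_, grp in per_well.groupby(["sirna", "insulin_nM", "cell_line"],
                                       dropna=False):
        for col in ("droplet_total", "droplet_count_mean", "droplet_area_mean"):
            vals = grp[col].dropna()
            rows.append(dict(zip(["sirna", "insulin_nM", "cell_line"], keys_),
                             readout=col, mean=vals.mean(),
                             sd=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                             n_wells=len(vals)))
    return pd.DataFrame(rows)
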
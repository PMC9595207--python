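"""Cross-plate anchored linear normalization and figure-scale summaries.

Plates are put on a common intensity scale using the control wells carried
on every plate: for plate *i*, let ``med0_i`` and ``med100_i`` be the medians
of control 0 nM and control 100 nM insulin cells, and let ``maxmed0`` and
``maxmed100`` be the maxima of those medians across plates. Each plate is
then linearly transformed so its control medians map exactly onto the
common anchors::

    Xnorm_i = (X_i - med0_i) * (maxmed100 - maxmed0) / (med100_i - med0_i) + maxmed0

followed by a log2 transform for single-cell distribution work. Cells whose
normalized value is non-positive are excluded from the log2 column (the
count is recorded) rather than floored, which would distort the left tail
of the single-cell histograms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ROLE_CONTROL_BASAL, ROLE_CONTROL_MAX

log = logging.getLogger(__name__)


@dataclass
class PlateAnchors:
    channel: str
    per_plate: pd.DataFrame     # plate, med0, med100
    maxmed0: float
    maxmed100: float
    n_nonpositive: int = 0      # cells excluded from the log2 column

    def to_json(self) -> str:
        return json.dumps({
            "channel": self.channel,
            "maxmed0": self.maxmed0,
            "maxmed100": self.maxmed100,
            "n_nonpositive": self.n_nonpositive,
            "per_plate": self.per_plate.to_dict(orient="records"),
        }, indent=2)


def plate_normalize(cells: pd.DataFrame, design: pd.DataFrame, channel: str,
                    adipocyte_col: str = "adipocyte"):
    """Anchor every plate's control medians to the cross-plate maxima.

    ``cells`` should already be gated (or carry a boolean ``adipocyte``
    column, in which case medians use gated cells only — the transform is
    still applied to every row). Adds ``<channel>_norm`` and
    ``log2_<channel>_norm`` columns; returns ``(table, PlateAnchors)``.
    """
    if channel not in cells.columns:
        raise ValueError(f"channel {channel!r} not in cell table")
    roles = design[["plate", "well", "role"]]
    merged = cells.merge(roles, on=["plate", "well"], how="left")
    use = merged[adipocyte_col] if adipocyte_col in merged.columns else slice(None)

    anchors = []
    for plate, grp in merged.groupby("plate", sort=True):
        g = grp if isinstance(use, slice) else grp[grp[adipocyte_col]]
        basal = g.loc[g["role"] == ROLE_CONTROL_BASAL, channel]
        maxi = g.loc[g["role"] == ROLE_CONTROL_MAX, channel]
        if basal.empty or maxi.empty:
            raise ValueError(
                f"plate {plate}: missing control-basal or control-100 nM "
                f"cells; cannot anchor normalization")
        med0, med100 = float(basal.median()), float(maxi.median())
        if med100 <= med0:
            raise ValueError(
                f"plate {plate}: control 100 nM median ({med100:g}) does not "
                f"exceed basal median ({med0:g}); plate is non-responsive")
        anchors.append(dict(plate=plate, med0=med0, med100=med100))
    per_plate = pd.DataFrame(anchors)
    maxmed0 = float(per_plate["med0"].max())
    maxmed100 = float(per_plate["med100"].max())

    out = cells.copy()
    x = out[channel].to_numpy(dtype=float)
    norm = np.empty_like(x)
    lut = per_plate.set_index("plate")
    for plate in lut.index:
        m = (out["plate"] == plate).to_numpy()
        med0, med100 = lut.loc[plate, "med0"], lut.loc[plate, "med100"]
        scale = (maxmed100 - maxmed0) / (med100 - med0)
        norm[m] = (x[m] - med0) * scale + maxmed0
    out[f"{channel}_norm"] = norm

    pos = norm > 0
    n_nonpos = int((~pos).sum())
    if n_nonpos:
        log.info("%s: %d cell(s) with non-positive normalized intensity "
                 "excluded from log2", channel, n_nonpos)
    log2n = np.full_like(norm, np.nan)
    np.log2(norm, out=log2n, where=pos)
    out[f"log2_{channel}_norm"] = log2n

    return out, PlateAnchors(channel=channel, per_plate=per_plate,
                             maxmed0=maxmed0, maxmed100=maxmed100,
                             n_nonpositive=n_nonpos)


def fold_over_basal(condition_means: pd.Series, basal_mean: float) -> pd.Series:
    """Fold over basal: per-condition mean divided by the matched basal mean."""
    if basal_mean <= 0:
        raise ValueError("basal mean must be positive")
    return condition_means / basal_mean


def minmax_percent(x, basal_ctrl: float, max_ctrl: float):
    """Min:max scale anchored at control basal (0%) and control 100 nM (100%).

    Linear with no clamping: values above the maximal control exceed 100%.
    """
    if max_ctrl <= basal_ctrl:
        raise ValueError("max control must exceed basal control")
    return 100.0 * (np.asarray(x, dtype=float) - basal_ctrl) / (max_ctrl - basal_ctrl)


def surface_over_total(cells: pd.DataFrame,
                       surface_channel: str = "glut4_surface",
                       total_channel: str = "total_reporter"):
    """Per-cell surface/total reporter ratio (e.g., HA over mRuby3 signal).

    Cells with a non-positive total are excluded; returns ``(ratio, n_excluded)``
    with the ratio indexed like the retained rows.
    """
    for col in (surface_channel, total_channel):
        if col not in cells.columns:
            raise ValueError(f"column {col!r} not in cell table")
    total = cells[total_channel].astype(float)
    ok = total > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("surface_over_total: %d cell(s) with non-positive total "
                 "excluded", n_excluded)
    ratio = cells.loc[ok, surface_channel].astype(float) / total[ok]
    return ratio.rename("surface_over_total"), n_excluded


def fold_over_control(summary: pd.DataFrame, value_col: str = "mean",
                      condition_col: str = "sirna", control_label: str = "NT",
                      strata=("insulin_nM", "cell_line")) -> pd.DataFrame:
    """Fold over (non-targeting) control, stratified by insulin dose and line.

    ``summary`` has one row per (condition x stratum) with a ``value_col``
    column of per-condition means. Adds an ``foc`` column.
    """
    strata = [s for s in strata if s in summary.columns]
    out = summary.copy()
    ctrl = out[out[condition_col] == control_label]
    if ctrl.empty:
        raise ValueError(f"no control condition {control_label!r} in summary")
    key = strata if strata else None
    if key:
        ref = ctrl.set_index(key)[value_col]
        idx = pd.MultiIndex.from_frame(out[key]) if len(key) > 1 else out[key[0]]
        denom = ref.reindex(idx).to_numpy()
        if np.isnan(denom).any():
            missing = out.loc[np.isnan(denom), key].drop_duplicates()
            raise ValueError(
                f"missing control stratum for: {missing.to_dict(orient='records')}")
    else:
        denom = float(ctrl[value_col].iloc[0])
    out["foc"] = out[value_col].to_numpy(dtype=float) / denom
    return out
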
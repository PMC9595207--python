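"""Adipocyte gating, nuclei counting and well-level QC.

Differentiated adipocyte cultures contain residual fibroblasts and necrotic
cells; adipocytes are distinguished by high light scatter from their lipid
droplets. Gating thresholds the per-cell ``lipid_scatter`` feature, either
at a fixed value or at the two-class minimum-within-class-variance (Otsu)
split of the pooled scatter values — by default computed on control wells
only, so treatment effects cannot bias the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)


@dataclass
class GateResult:
    adipocyte: pd.Series          # boolean flag, aligned with the cell table
    threshold: float              # scatter units actually applied
    method: str                   # "fixed" or "otsu"
    well_counts: pd.DataFrame     # plate, well, n_total, n_gated


def gate_adipocytes(cells: pd.DataFrame, method: str = "otsu",
                    threshold: Optional[float] = None,
                    reference: Optional[pd.DataFrame] = None) -> GateResult:
    """Flag adipocytes as cells with ``lipid_scatter >= threshold``.

    Parameters
    ----------
    method
        ``"fixed"`` uses the supplied threshold; ``"otsu"`` derives it as the
        two-class variance-minimizing split of the reference scatter values.
    reference
        Cell rows used to derive the automatic threshold (typically the
        control wells); defaults to all cells. The threshold is then applied
        to every well.
    """
    scatter = cells["lipid_scatter"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scatter)):
        raise ValueError("lipid_scatter contains non-finite values")

    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed gating requires an explicit threshold")
        thr = float(threshold)
    elif method == "otsu":
        ref = (reference if reference is not None else cells)
        vals = ref["lipid_scatter"].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            raise ValueError(
                "all scatter values identical: no separable classes for "
                "automatic gating")
        thr = float(threshold_otsu(vals))
    else:
        raise ValueError(f"unknown gating method {method!r}")

    flag = pd.Series(scatter >= thr, index=cells.index, name="adipocyte")
    counts = (
        cells.assign(adipocyte=flag)
        .groupby(["plate", "well"], sort=True)
        .agg(n_total=("adipocyte", "size"), n_gated=("adipocyte", "sum"))
        .reset_index()
    )
    return GateResult(adipocyte=flag, threshold=thr, method=method,
                      well_counts=counts)


def count_nuclei(cells: pd.DataFrame) -> pd.DataFrame:
    """Nuclei per field of view: exact row counts per (plate, well, field)."""
    if cells.empty:
        warnings.warn("empty cell table: no nuclei to count")
        return pd.DataFrame(columns=["plate", "well", "field", "n_nuclei"])
    return (cells.groupby(["plate", "well", "field"], sort=True)
            .size().rename("n_nuclei").reset_index())


def well_qc(gate: GateResult, min_cells: int = 50) -> pd.DataFrame:
    """Flag wells whose gated adipocyte count falls below ``min_cells``.

    Returns the per-well count table with a boolean ``qc_pass`` column;
    failing wells are meant to be dropped from every downstream summary.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    out = gate.well_counts.copy()
    out["qc_pass"] = out["n_gated"] >= min_cells
    n_fail = int((~out["qc_pass"]).sum())
    if n_fail:
        failed = out.loc[~out["qc_pass"], ["plate", "well"]]
        log.info("well QC: %d well(s) excluded (< %d gated cells): %s",
                 n_fail, min_cells,
                 ", ".join(f"{p}/{w}" for p, w in failed.itertuples(index=False)))
    return out


def apply_gate(cells: pd.DataFrame, gate: GateResult,
               qc: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Return the gated (and optionally QC-passing) subset of the cell table."""
    out = cells.loc[gate.adipocyte.to_numpy()].copy()
    if qc is not None:
        ok = qc.loc[qc["qc_pass"], ["plate", "well"]]
        out = out.merge(ok, on=["plate", "well"], how="inner")
    return out
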
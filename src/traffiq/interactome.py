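"""Bait-vs-IgG AP-MS differential enrichment and insulin-regulation calls.

Input is a MaxQuant-style protein-groups table (one row per protein group,
``LFQ intensity <sample>`` columns with 0 meaning not quantified, and
``Reverse`` / ``Potential contaminant`` / ``Only identified by site`` flag
columns) together with a sample design mapping each sample to
(bait | IgG) x (basal | insulin) x replicate.

Processing order:

1. filter decoys/contaminants/site-only IDs and sparsely quantified proteins;
2. log2 transform and median-normalize per sample;
3. average each IgG replicate across the two conditions to a single control;
4. two-step imputation — within-condition Normal(mean, SD) where >= 2
   replicates were quantified, then a downshifted Normal
   (mean - 1 SD, 0.6 SD, per sample) for remaining missing IgG values;
5. per-condition bait-vs-IgG two-sample t tests on fully quantified
   proteins, Benjamini-Hochberg correction per condition;
6. classification: a protein is "insulin-regulated" when the bait-IgG
   log2 fold-change differs between insulin and basal by more than 2x the
   raw (unscaled) MAD of that difference across all tested proteins, the
   fold-change exceeds 2 in at least one condition, and the adjusted p in
   that same condition is <= 0.05.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FLAG_COLUMNS = ["Reverse", "Potential contaminant", "Only identified by site"]
LFQ_PREFIX = "LFQ intensity "

CLASS_NOT_ENRICHED = "not enriched"
CLASS_ENRICHED = "enriched"
CLASS_REGULATED = "insulin-regulated"


# --------------------------------------------------------------------------
# table handling

def lfq_matrix(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Extract the protein x sample intensity matrix (NaN = not quantified)."""
    cols = {}
    for s in design["sample"]:
        col = LFQ_PREFIX + s
        if col not in table.columns:
            raise ValueError(f"missing LFQ column for sample {s!r}")
        cols[s] = table[col].to_numpy(dtype=float)
    mat = pd.DataFrame(cols, index=table["Protein IDs"].to_numpy())
    return mat.where(mat > 0)


def _bait_condition_counts(mat: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    counts = {}
    bait = design[design["group"] == "bait"]
    for cond, sub in bait.groupby("condition"):
        counts[cond] = mat[list(sub["sample"])].notna().sum(axis=1)
    return pd.DataFrame(counts)


def filter_protein_groups(table: pd.DataFrame, design: pd.DataFrame,
                          min_quantified: int = 2,
                          sparse_rule: str = "every_condition"
                          ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Remove flagged rows and sparsely quantified proteins.

    A protein is dropped for sparsity when it has fewer than
    ``min_quantified`` values in *every* bait condition
    (``sparse_rule="every_condition"``, default) or across all bait samples
    pooled (``sparse_rule="across_all"``). Returns the retained table and
    per-reason removal counts.
    """
    keep = pd.Series(True, index=table.index)
    removed: Dict[str, int] = {}
    for col in FLAG_COLUMNS:
        if col in table.columns:
            flagged = table[col].fillna("").astype(str).str.strip() == "+"
            removed[col] = int((flagged & keep).sum())
            keep &= ~flagged

    mat = lfq_matrix(table, design)
    counts = _bait_condition_counts(mat, design)
    if sparse_rule == "every_condition":
        sparse = (counts < min_quantified).all(axis=1)
    elif sparse_rule == "across_all":
        sparse = counts.sum(axis=1) < min_quantified
    else:
        raise ValueError(f"unknown sparse_rule {sparse_rule!r}")
    sparse = pd.Series(sparse.to_numpy(), index=table.index)
    removed["sparse"] = int((sparse & keep).sum())
    keep &= ~sparse
    for reason, n in removed.items():
        if n:
            log.info("filter_protein_groups: removed %d row(s) for %s", n, reason)
    return table[keep].reset_index(drop=True), removed


def log2_median_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Log2 transform and equalize per-sample medians.

    Each sample's median (over its quantified values) is shifted to the
    grand median of sample medians so the pooled intensity scale is kept;
    missing values stay missing.
    """
    if (mat <= 0).any().any():
        raise ValueError("intensities must be positive where quantified")
    logm = np.log2(mat)
    med = logm.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"sample(s) with no quantified values: {bad}")
    return logm - med + med.median()


def average_igg(mat: pd.DataFrame, design: pd.DataFrame
                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Merge each IgG replicate across basal/insulin into one control column.

    On the log2 scale, ``IgG_r = mean(IgG_basal_r, IgG_insulin_r)``; if one
    partner is missing the present value is carried. The merged IgG set is
    the control for both bait conditions. Returns the new matrix and design.
    """
    igg = design[design["group"] == "IgG"]
    if igg.empty:
        raise ValueError("no IgG samples in design")
    out = mat[list(design.loc[design["group"] == "bait", "sample"])].copy()
    rows = design[design["group"] == "bait"].copy()
    for r, sub in igg.groupby("replicate"):
        cols = list(sub["sample"])
        merged = mat[cols].mean(axis=1, skipna=True)  # carries single partner
        name = f"IgG_{r}"
        out[name] = merged
        rows = pd.concat([rows, pd.DataFrame([dict(
            sample=name, group="IgG", condition="both", replicate=r)])],
            ignore_index=True)
    return out, rows


def impute_two_step(mat: pd.DataFrame, design: pd.DataFrame, seed: int
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step missing-value imputation on the log2 scale.

    Step 1 (per protein x condition group): if >= 2 replicates are
    quantified, draw the missing ones from Normal(mean, SD) of the
    quantified replicates. Step 2 (IgG controls only): remaining missing
    values are drawn per sample from the downshifted Normal
    (sample mean - 1 x sample SD, 0.6 x sample SD) over that sample's
    quantified values. The mask records 0 = observed, 1 = step 1,
    2 = step 2, -1 = still missing.
    """
    rng = np.random.default_rng(seed)
    out = mat.copy()
    mask = pd.DataFrame(0, index=mat.index, columns=mat.columns, dtype=int)
    mask[mat.isna()] = -1

    for (_, _), sub in design.groupby(["group", "condition"]):
        cols = list(sub["sample"])
        block = out[cols]
        vals = block.to_numpy(dtype=float)
        nq = np.sum(~np.isnan(vals), axis=1)
        fill_rows = np.flatnonzero((nq >= 2) & (nq < len(cols)))
        for i in fill_rows:
            row = vals[i]
            miss = np.isnan(row)
            mu, sd = np.nanmean(row), np.nanstd(row, ddof=1)
            draws = rng.normal(mu, sd, size=miss.sum())
            row[miss] = draws
            vals[i] = row
            for j in np.flatnonzero(miss):
                mask.iloc[i, mask.columns.get_loc(cols[j])] = 1
        out[cols] = vals

    igg_cols = list(design.loc[design["group"] == "IgG", "sample"])
    for c in igg_cols:
        col = out[c].to_numpy(dtype=float)
        miss = np.isnan(col)
        if not miss.any():
            continue
        mu, sd = np.nanmean(col), np.nanstd(col, ddof=1)
        col[miss] = rng.normal(mu - sd, 0.6 * sd, size=miss.sum())
        out[c] = col
        mask.loc[miss, c] = 2
    return out, mask


def differential_enrichment(mat: pd.DataFrame, design: pd.DataFrame,
                            equal_var: bool = True,
                            pooled_bh: bool = False) -> pd.DataFrame:
    """Per-protein, per-condition bait-vs-IgG log2FC, t test and BH-adjusted p.

    Proteins still containing missing values are excluded from testing
    (``tested`` False). Zero within-group variance in both groups leaves the
    p-value NaN with ``degenerate`` True. BH runs within each condition by
    default; ``pooled_bh`` adjusts basal and insulin p-values together.
    """
    igg_cols = list(design.loc[design["group"] == "IgG", "sample"])
    res = pd.DataFrame(index=mat.index)
    complete = mat.notna().all(axis=1)
    res["tested"] = complete
    n_skip = int((~complete).sum())
    if n_skip:
        log.info("differential_enrichment: %d protein(s) still missing values "
                 "after imputation, excluded from testing", n_skip)

    for cond in ("basal", "insulin"):
        bait_cols = list(design.loc[(design["group"] == "bait")
                                    & (design["condition"] == cond), "sample"])
        bait = mat[bait_cols].to_numpy(dtype=float)
        ctrl = mat[igg_cols].to_numpy(dtype=float)
        # rows with residual NaN propagate NaN here and are masked below
        import warnings as _warnings
        with np.errstate(invalid="ignore", divide="ignore"), \
                _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            fc = np.nanmean(bait, axis=1) - np.nanmean(ctrl, axis=1)
            tt = stats.ttest_ind(bait, ctrl, axis=1, equal_var=equal_var)
            t, p = np.asarray(tt.statistic, float), np.asarray(tt.pvalue, float)
            degen = ((np.nanvar(bait, axis=1) == 0)
                     & (np.nanvar(ctrl, axis=1) == 0))
        p[degen] = np.nan
        t[degen] = np.nan
        keep = complete.to_numpy()
        res[f"log2fc_{cond}"] = np.where(keep, fc, np.nan)
        res[f"t_{cond}"] = np.where(keep, t, np.nan)
        res[f"p_{cond}"] = np.where(keep, p, np.nan)
        res[f"degenerate_{cond}"] = degen & keep

    if pooled_bh:
        cols = ["p_basal", "p_insulin"]
        flat = res[cols].to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        adj = adj.reshape(-1, 2)
        res["padj_basal"], res["padj_insulin"] = adj[:, 0], adj[:, 1]
    else:
        for cond in ("basal", "insulin"):
            p = res[f"p_{cond}"].to_numpy()
            ok = np.isfinite(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            res[f"padj_{cond}"] = adj
    return res


def classify_insulin_regulated(enrichment: pd.DataFrame,
                               fc_threshold: float = 2.0,
                               mad_multiplier: float = 2.0,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Label proteins not enriched / enriched / insulin-regulated.

    Delta = log2FC(insulin) - log2FC(basal); its raw MAD (no 1.4826 scaling)
    over all tested proteins sets the regulation threshold. A protein is
    enriched when log2FC > ``fc_threshold`` with adjusted p <= ``alpha`` in
    at least one condition, and insulin-regulated when additionally
    |Delta| > ``mad_multiplier`` x MAD.
    """
    tested = enrichment["tested"]
    if int(tested.sum()) < 3:
        raise ValueError("fewer than 3 tested proteins: MAD unreliable")
    out = enrichment.copy()
    delta = out["log2fc_insulin"] - out["log2fc_basal"]
    out["delta_log2fc"] = delta
    d = delta[tested].to_numpy()
    mad = float(np.median(np.abs(d - np.median(d))))
    out["mad_delta"] = mad

    enriched_any = pd.Series(False, index=out.index)
    for cond in ("basal", "insulin"):
        enriched_any |= ((out[f"log2fc_{cond}"] > fc_threshold)
                         & (out[f"padj_{cond}"] <= alpha))
    regulated = enriched_any & (delta.abs() > mad_multiplier * mad)
    out["class"] = CLASS_NOT_ENRICHED
    out.loc[enriched_any.fillna(False), "class"] = CLASS_ENRICHED
    out.loc[regulated.fillna(False), "class"] = CLASS_REGULATED
    out.loc[~tested, "class"] = CLASS_NOT_ENRICHED
    return out


def run_ipms_pipeline(table: pd.DataFrame, design: pd.DataFrame, seed: int,
                      sparse_rule: str = "every_condition",
                      equal_var: bool = True,
                      pooled_bh: bool = False) -> pd.DataFrame:
    """Full protein-groups -> enrichment-classes pipeline (steps 1-6)."""
    filtered, _ = filter_protein_groups(table, design, sparse_rule=sparse_rule)
    mat = lfq_matrix(filtered, design)
    mat = log2_median_normalize(mat)
    mat, merged_design = average_igg(mat, design)
    mat, _mask = impute_two_step(mat, merged_design, seed)
    res = differential_enrichment(mat, merged_design, equal_var=equal_var,
                                  pooled_bh=pooled_bh)
    return classify_insulin_regulated(res)
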
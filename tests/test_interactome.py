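"""AP-MS enrichment pipeline: filters, normalization, IgG merging,
two-step imputation, t tests with BH correction, and the MAD-based
insulin-regulation rule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from traffiq.interactome import (CLASS_REGULATED, average_igg,
                                 classify_insulin_regulated,
                                 differential_enrichment,
                                 filter_protein_groups, impute_two_step,
                                 lfq_matrix, log2_median_normalize,
                                 run_ipms_pipeline)
from traffiq.synthetic_data import IpmsSimConfig, ipms_sample_names, preset, simulate_ipms


def _design(n_reps=3):
    return ipms_sample_names(n_reps)[1]


def _table(rows, design, flags=None):
    """rows: dict protein -> per-sample linear intensities (0 = missing)."""
    samples = list(design["sample"])
    t = pd.DataFrame({"Protein IDs": list(rows)})
    vals = np.array(list(rows.values()), dtype=float)
    for j, s in enumerate(samples):
        t[f"LFQ intensity {s}"] = vals[:, j]
    for col in ("Reverse", "Potential contaminant", "Only identified by site"):
        t[col] = ""
    if flags:
        for protein, col in flags.items():
            t.loc[t["Protein IDs"] == protein, col] = "+"
    return t


class TestFilter:
    def test_five_row_toy(self):
        design = _design()
        full = [1000.0] * 12
        sparse = [1000, 0, 0, 1000, 0, 0] + [1000.0] * 6  # 1 per bait condition
        rows = {"rev": full, "cont": full, "site": full,
                "sparse": sparse, "ok": full}
        table = _table(rows, design, flags={
            "rev": "Reverse", "cont": "Potential contaminant",
            "site": "Only identified by site"})
        kept, removed = filter_protein_groups(table, design)
        assert list(kept["Protein IDs"]) == ["ok"]
        assert removed == {"Reverse": 1, "Potential contaminant": 1,
                           "Only identified by site": 1, "sparse": 1}

    def test_clean_table_unchanged(self):
        design = _design()
        table = _table({"a": [100.0] * 12, "b": [200.0] * 12}, design)
        kept, removed = filter_protein_groups(table, design)
        assert len(kept) == 2 and removed["sparse"] == 0

    def test_one_quantified_condition_is_enough_by_default(self):
        # quantified twice in bait-basal, never in bait-insulin: retained
        # under the "every bait condition sparse" reading, removed under
        # the pooled "across all bait samples" reading only if total < 2
        design = _design()
        vals = [1000, 1000, 0, 0, 0, 0] + [1000.0] * 6
        table = _table({"p": vals}, design)
        kept, _ = filter_protein_groups(table, design)
        assert list(kept["Protein IDs"]) == ["p"]
        kept2, _ = filter_protein_groups(table, design,
                                         sparse_rule="across_all")
        assert list(kept2["Protein IDs"]) == ["p"]


class TestNormalize:
    def test_single_sample_log2_preserved(self):
        m = pd.DataFrame({"s": [4.0, 16.0, 64.0]})
        out = log2_median_normalize(m)
        np.testing.assert_allclose(out["s"], [2.0, 4.0, 6.0])

    def test_constant_factor_offset_removed(self):
        rng = np.random.default_rng(0)
        a = 2.0 ** rng.normal(20, 2, 50)
        m = pd.DataFrame({"s1": a, "s2": a * 8.0})
        out = log2_median_normalize(m)
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_medians_equalized_on_simulated_matrix(self):
        (table, design), _ = simulate_ipms(IpmsSimConfig(n_proteins=300, seed=3))
        mat = lfq_matrix(table, design)
        out = log2_median_normalize(mat)
        med = out.median(axis=0, skipna=True)
        np.testing.assert_allclose(med, med.iloc[0], rtol=1e-12)


class TestAverageIgg:
    def test_pairwise_mean(self):
        design = _design(n_reps=2)
        mat = lfq_matrix(_table({"p": [100.0] * 8}, design), design)
        mat = np.log2(mat)
        mat.loc["p", "IgG_basal_1"] = 20.0
        mat.loc["p", "IgG_insulin_1"] = 22.0
        out, merged = average_igg(mat, design)
        assert out.loc["p", "IgG_1"] == 21.0
        assert set(merged.loc[merged["group"] == "IgG", "sample"]) == {"IgG_1", "IgG_2"}

    def test_identical_conditions_identity(self):
        design = _design(n_reps=2)
        mat = np.log2(lfq_matrix(_table({"p": [100.0] * 8}, design), design))
        out, _ = average_igg(mat, design)
        assert out.loc["p", "IgG_1"] == np.log2(100.0)

    def test_missing_partner_carried_forward(self):
        design = _design(n_reps=2)
        table = _table({"p": [100.0] * 8}, design)
        table["LFQ intensity IgG_insulin_1"] = 0.0  # missing partner
        mat = np.log2(lfq_matrix(table, design))
        out, _ = average_igg(mat, design)
        assert out.loc["p", "IgG_1"] == np.log2(100.0)

    def test_no_igg_rejected(self):
        design = _design()
        bait_only = design[design["group"] == "bait"]
        mat = np.log2(lfq_matrix(_table({"p": [100.0] * 12}, design), design))
        with pytest.raises(ValueError):
            average_igg(mat[list(bait_only["sample"])], bait_only)


class TestImputation:
    def test_complete_table_untouched(self):
        design = _design()
        mat = np.log2(lfq_matrix(_table({"p": [100.0] * 12}, design), design))
        out, mask = impute_two_step(mat, design, seed=0)
        pd.testing.assert_frame_equal(out, mat)
        assert (mask == 0).all().all()

    def test_step1_draw_matches_independent_reimplementation(self):
        # one protein, bait-basal replicates {20, 22, missing}: the draw must
        # equal Normal(21, sd({20,22})) from the same fresh generator state
        design = _design()
        design = design[(design["group"] == "bait")
                        & (design["condition"] == "basal")]
        mat = pd.DataFrame([[20.0, 22.0, np.nan]], index=["p"],
                           columns=list(design["sample"]))
        out, mask = impute_two_step(mat, design, seed=99)
        expected = np.random.default_rng(99).normal(
            21.0, np.std([20.0, 22.0], ddof=1), 1)[0]
        assert out.iloc[0, 2] == pytest.approx(expected, rel=1e-12)
        assert mask.iloc[0, 2] == 1

    def test_step2_downshift_moments(self):
        # IgG column built to have mean 25, SD 2 over quantified values;
        # step-2 draws should average mu - sd with SD 0.6*sd
        rng = np.random.default_rng(12)
        n_missing = 10000
        quantified = rng.normal(25.0, 2.0, 50000)
        col = np.concatenate([quantified, np.full(n_missing, np.nan)])
        design = pd.DataFrame([dict(sample="IgG_1", group="IgG",
                                    condition="both", replicate=1)])
        mat = pd.DataFrame({"IgG_1": col},
                           index=[f"p{i}" for i in range(len(col))])
        out, mask = impute_two_step(mat, design, seed=12)
        drawn = out["IgG_1"].to_numpy()[np.isnan(col)]
        mu, sd = quantified.mean(), quantified.std(ddof=1)
        assert drawn.mean() == pytest.approx(mu - sd,
                                             abs=3 * 0.6 * sd / np.sqrt(n_missing))
        assert drawn.std(ddof=1) == pytest.approx(
            0.6 * sd, abs=3 * 0.6 * sd / np.sqrt(2 * n_missing))
        assert (mask["IgG_1"].to_numpy()[np.isnan(col)] == 2).all()

    def test_quantified_values_never_altered(self):
        cfg = IpmsSimConfig(n_proteins=200, seed=4)
        (table, design), _ = simulate_ipms(cfg)
        mat = log2_median_normalize(lfq_matrix(table, design))
        merged, mdesign = average_igg(mat, design)
        out, mask = impute_two_step(merged, mdesign, seed=4)
        untouched = mask == 0
        pd.testing.assert_frame_equal(out[untouched], merged[untouched])


def brute_force_bh(pvals):
    """Step-up BH from the definition: adj_i = min over j>=i of p_(j)*m/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestEnrichment:
    def test_degenerate_variance_flagged(self):
        design = _design()
        mat = pd.DataFrame(
            [[5.0] * 3 + [5.0] * 3 + [1.0] * 6],
            index=["p"], columns=list(_design()["sample"]))
        res = differential_enrichment(mat, design)
        assert res.loc["p", "log2fc_basal"] == pytest.approx(4.0)
        assert bool(res.loc["p", "degenerate_basal"])
        assert np.isnan(res.loc["p", "p_basal"])

    def test_bh_worked_example(self):
        adj = multipletests([0.005, 0.01, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_bh_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m)
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], brute_force_bh(p),
                rtol=1e-12)

    def test_null_matrix_controls_fdr(self):
        cfg = IpmsSimConfig(n_proteins=1000, enrichment_log2_effect=0.0,
                            dropout_midpoint=-100.0, flag_fraction=0.0,
                            seed=13)
        (table, design), _ = simulate_ipms(cfg)
        mat = log2_median_normalize(lfq_matrix(table, design))
        merged, mdesign = average_igg(mat, design)
        res = differential_enrichment(merged, mdesign)
        for cond in ("basal", "insulin"):
            frac = (res[f"padj_{cond}"] <= 0.05).mean()
            assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)


class TestClassification:
    def _enrichment(self, deltas, fc=5.0, padj=0.001):
        n = len(deltas)
        return pd.DataFrame({
            "tested": [True] * n,
            "log2fc_basal": [fc] * n,
            "log2fc_insulin": [fc + d for d in deltas],
            "padj_basal": [padj] * n,
            "padj_insulin": [padj] * n,
        }, index=[f"p{i}" for i in range(n)])

    def test_mad_worked_example(self):
        # deltas [-0.2,-0.1,0,0.1,0.2,3.0]: median 0.05, MAD 0.15,
        # threshold 0.30 -> only the delta=3.0 protein is regulated
        enr = self._enrichment([-0.2, -0.1, 0.0, 0.1, 0.2, 3.0])
        out = classify_insulin_regulated(enr)
        assert out["mad_delta"].iloc[0] == pytest.approx(0.15)
        regulated = out.index[out["class"] == CLASS_REGULATED]
        assert list(regulated) == ["p5"]

    def test_zero_mad_blocks_all(self):
        out = classify_insulin_regulated(self._enrichment([0.0] * 6))
        assert (out["class"] != CLASS_REGULATED).all()

    def test_too_few_tested_rejected(self):
        enr = self._enrichment([0.0, 1.0])
        with pytest.raises(ValueError):
            classify_insulin_regulated(enr)

    def test_row_order_invariance(self):
        enr = self._enrichment([-0.2, -0.1, 0.0, 0.1, 0.2, 3.0])
        shuffled = enr.sample(frac=1.0, random_state=5)
        out1 = classify_insulin_regulated(enr)
        out2 = classify_insulin_regulated(shuffled).loc[out1.index]
        assert list(out1["class"]) == list(out2["class"])


class TestEndToEnd:
    def test_planted_truth_recovered(self):
        cfg = preset("ipms_default", seed=14)
        (table, design), truth = simulate_ipms(cfg)
        res = run_ipms_pipeline(table, design, seed=14)
        called = set(res.index[res["class"] == CLASS_REGULATED])
        planted = set(truth.regulated_proteins)
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9
        assert len(called - planted) <= 1

    def test_pipeline_determinism(self):
        cfg = dataclasses.replace(preset("ipms_default", seed=6),
                                  n_proteins=300)
        (table, design), _ = simulate_ipms(cfg)
        r1 = run_ipms_pipeline(table, design, seed=6)
        r2 = run_ipms_pipeline(table, design, seed=6)
        pd.testing.assert_frame_equal(r1, r2)
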
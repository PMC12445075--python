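"""Single-cell stage: QC gates, stratification, extreme DE, enrichment, CNV."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import stressig as sg
from stressig import scrna


def toy_adata(rng, n_cells=100, n_genes=600, n_mt=10, n_ribo=10):
    """Baseline matrix where every cell comfortably passes every gate."""
    X = rng.poisson(2.0, size=(n_cells, n_genes))
    dense = min(300, n_genes - n_mt - n_ribo)
    X[:, :dense] = rng.poisson(5.0, size=(n_cells, dense))  # ensure many detected genes
    genes = [f"g{i}" for i in range(n_genes - n_mt - n_ribo)] + \
            [f"MT-{i}" for i in range(n_mt)] + [f"RP-{i}" for i in range(n_ribo)]
    var = pd.DataFrame(
        {"is_mt": [g.startswith("MT-") for g in genes],
         "is_ribo": [g.startswith("RP-") for g in genes],
         "position": np.arange(n_genes)},
        index=genes,
    )
    obs = pd.DataFrame(index=[f"c{i:03d}" for i in range(n_cells)])
    return ad.AnnData(X=X, obs=obs, var=var)


class TestQCFilter:
    def test_constructed_toy_86_survivors(self, rng):
        adata = toy_adata(rng)
        X = np.asarray(adata.X)
        # 7 cells with <200 detected genes, 5 with mt_frac > 0.15, 2 with huge
        # gene counts (disjoint sets) -> 86 survivors
        X[:7, :] = 0
        X[:7, :100] = 1
        mt_cols = adata.var["is_mt"].to_numpy()
        X[7:12, mt_cols] = X[7:12].sum(axis=1)[:, None]  # MT dominates
        X[12:14, :] = np.maximum(X[12:14, :], 1)  # detect every gene
        adata.X = X
        out, report = scrna.qc_filter(adata)
        assert report.removed_low_genes == 7
        assert report.removed_high_mt == 5
        assert report.removed_high_count == 2
        assert out.n_obs == 86

    def test_all_pass_unchanged(self, rng):
        adata = toy_adata(rng)
        out, report = scrna.qc_filter(adata)
        assert out.n_obs == adata.n_obs - report.removed_high_count
        assert report.removed_low_genes == report.removed_high_mt == 0

    def test_matches_literal_definition_oracle(self, rng):
        adata = toy_adata(rng, n_cells=150)
        X = np.asarray(adata.X)
        X[rng.random(X.shape) < 0.4] = 0
        adata.X = X
        out, _ = scrna.qc_filter(adata, min_genes=150, min_cells=5)
        # independent re-implementation of the gate sequence
        keep = (X > 0).sum(axis=1) >= 150
        Xc = X[keep]
        gene_keep = (Xc > 0).sum(axis=0) >= 5
        Xc = Xc[:, gene_keep]
        tot = Xc.sum(axis=1).astype(float)
        tot[tot == 0] = 1
        mt = Xc[:, adata.var["is_mt"].to_numpy()[gene_keep]].sum(axis=1) / tot
        rb = Xc[:, adata.var["is_ribo"].to_numpy()[gene_keep]].sum(axis=1) / tot
        keep2 = (mt <= 0.15) & (rb <= 0.15)
        Xc = Xc[keep2]
        ng = (Xc > 0).sum(axis=1)
        keep3 = ng <= np.percentile(ng, 98)
        assert out.n_obs == keep3.sum()
        assert out.n_vars == gene_keep.sum()

    def test_missing_flags_rejected(self, rng):
        adata = toy_adata(rng)
        adata.var = adata.var.drop(columns=["is_mt"])
        with pytest.raises(ValueError):
            scrna.qc_filter(adata)


class TestStratify:
    @pytest.fixture()
    def normed(self, rng):
        adata = toy_adata(rng, n_cells=200)
        return scrna.normalize_cells(adata)

    def test_unique_values_match_sort(self, rng):
        adata = toy_adata(rng, n_cells=100)
        scrna.normalize_cells(adata)
        gene = adata.var_names[0]
        col = adata.var_names.get_loc(gene)
        # make values unique
        adata.layers["lognorm"][:, col] = rng.permutation(100).astype(float)
        strata = scrna.stratify_extremes(adata, gene, q=0.10)
        vals = adata.layers["lognorm"][:, col]
        top = set(np.argsort(-vals)[:10])
        got = set(np.flatnonzero((strata == "High").to_numpy()))
        assert got == top
        assert (strata == "High").sum() == (strata == "Low").sum() == 10

    def test_exact_floor_group_sizes(self, normed):
        strata = scrna.stratify_extremes(normed, normed.var_names[3], q=0.17)
        k = int(np.floor(0.17 * normed.n_obs))
        assert (strata == "High").sum() == k and (strata == "Low").sum() == k

    def test_zero_inflated_ties_deterministic(self, rng):
        adata = toy_adata(rng, n_cells=300)
        gene = adata.var_names[5]
        col = adata.var_names.get_loc(gene)
        X = np.asarray(adata.X)
        X[:, col] = 0
        nonzero = rng.random(300) > 0.6
        X[nonzero, col] = rng.integers(1, 5, size=int(nonzero.sum()))
        adata.X = X
        scrna.normalize_cells(adata)
        a = scrna.stratify_extremes(adata, gene, q=0.10)
        b = scrna.stratify_extremes(adata, gene, q=0.10)
        pd.testing.assert_series_equal(a, b)
        low_cells = a == "Low"
        assert (adata.layers["lognorm"][low_cells.to_numpy(), col] == 0).all()

    def test_too_small_groups_rejected(self, normed):
        with pytest.raises(ValueError):
            scrna.stratify_extremes(normed, normed.var_names[0], q=0.01)


class TestExtremeDE:
    def test_planted_shift_flagged_positive(self, rng):
        adata = toy_adata(rng, n_cells=400)
        scrna.normalize_cells(adata)
        strata = pd.Series("neither", index=adata.obs_names)
        strata.iloc[:100] = "High"
        strata.iloc[100:200] = "Low"
        shifted = list(adata.var_names[:5])
        idx = [adata.var_names.get_loc(g) for g in shifted]
        adata.layers["lognorm"][:100, idx] += 1.0
        de = scrna.extreme_de(adata, strata)
        assert de.loc[shifted, "significant"].all()
        assert (de.loc[shifted, "enrichment"] > 0.5).all()

    def test_constant_gene_null(self, rng):
        adata = toy_adata(rng, n_cells=100)
        scrna.normalize_cells(adata)
        adata.layers["lognorm"][:, 0] = 1.0
        strata = pd.Series("neither", index=adata.obs_names)
        strata.iloc[:30], strata.iloc[30:60] = "High", "Low"
        de = scrna.extreme_de(adata, strata)
        assert de.iloc[0]["enrichment"] == 0.0 and de.iloc[0]["p"] == 1.0

    def test_label_permutation_null(self, rng):
        adata = toy_adata(rng, n_cells=300)
        scrna.normalize_cells(adata)
        perm = rng.permutation(adata.n_obs)
        strata = pd.Series("neither", index=adata.obs_names)
        strata.iloc[perm[:80]] = "High"
        strata.iloc[perm[80:160]] = "Low"
        de = scrna.extreme_de(adata, strata)
        assert de["significant"].mean() <= 0.05 + 0.02


class TestEnrichmentFold:
    def test_degenerate_zero_cell_haldane(self):
        strata = pd.Series(["High"] * 10 + ["Low"] * 90 + ["Low"] * 100,
                           index=[f"c{i}" for i in range(200)])
        treatment = pd.Series(["treated"] * 100 + ["naive"] * 100,
                              index=strata.index)
        with pytest.warns(UserWarning):
            fold, table, corrected = scrna.enrichment_fold(strata, treatment)
        assert corrected and fold > 1
        assert table.loc["High", "naive"] == 0

    def test_missing_arm_rejected(self):
        strata = pd.Series(["High", "Low"], index=["a", "b"])
        treatment = pd.Series(["treated", "treated"], index=["a", "b"])
        with pytest.raises(ValueError):
            scrna.enrichment_fold(strata, treatment)

    def test_symmetric_data_fold_near_one(self, small_config, small_reference):
        import dataclasses

        cfg = dataclasses.replace(small_config, treated_enrichment=1.0, n_cells=4000)
        adata = sg.synthdata.simulate_scrna(cfg, small_reference)
        scrna.normalize_cells(adata)
        mal = adata[(adata.obs["cell_type"] == "epithelial")
                    & ~adata.obs["normal_adjacent"]].copy()
        strata = scrna.stratify_extremes(mal, small_reference.truth.itgb3_gene)
        fold, _, _ = scrna.enrichment_fold(strata, mal.obs["treatment"])
        assert 0.7 <= fold <= 1.4


class TestCnvWindow:
    def test_reference_identical_cell_zero_profile(self, rng):
        adata = toy_adata(rng, n_cells=50)
        scrna.normalize_cells(adata)
        ref_cells = list(adata.obs_names[:20])
        ref_mean = adata.layers["lognorm"][:20].mean(axis=0)
        adata.layers["lognorm"][49] = ref_mean  # plant a cell equal to the ref mean
        profile, burden = scrna.cnv_window_score(adata, ref_cells, window=25)
        np.testing.assert_allclose(profile[49], 0.0, atol=1e-12)
        assert burden.iloc[49] == pytest.approx(0.0, abs=1e-15)

    def test_window_one_equals_clipped_relative(self, rng):
        adata = toy_adata(rng, n_cells=40)
        scrna.normalize_cells(adata)
        ref_cells = list(adata.obs_names[:15])
        prof, _ = scrna.cnv_window_score(adata, ref_cells, window=1)
        X = adata.layers["lognorm"]
        mean = X[:15].mean(axis=0)
        sd = X[:15].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, sd[sd > 0].mean())
        expected = np.clip(X - mean, -3 * sd, 3 * sd)
        np.testing.assert_allclose(prof, expected)

    def test_planted_amplification_raises_burden(self, rng):
        adata = toy_adata(rng, n_cells=120, n_genes=800)
        scrna.normalize_cells(adata)
        ref_cells = list(adata.obs_names[:40])
        carriers = np.arange(60, 90)
        adata.layers["lognorm"][carriers, 100:600] += 0.5  # 500-gene amplification
        _, burden = scrna.cnv_window_score(adata, ref_cells, window=250)
        non_carriers = np.arange(90, 120)
        thresh = burden.iloc[non_carriers].max()
        n_above = (burden.iloc[carriers] > thresh).sum()
        assert n_above >= 29  # >= 19/20 of carriers exceed every non-carrier

    def test_oversized_window_rejected(self, rng):
        adata = toy_adata(rng, n_cells=10, n_genes=100)
        scrna.normalize_cells(adata)
        with pytest.raises(ValueError):
            scrna.cnv_window_score(adata, list(adata.obs_names[:3]), window=500)
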
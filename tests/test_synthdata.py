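"""Generator contracts: determinism, planted structure, recoverable effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import stressig as sg
from stressig import intervals as iv
from stressig import synthdata as sd

from conftest import SMALL


def overlap_oracle(peaks: pd.DataFrame, start: int, end: int) -> bool:
    return bool(((peaks["start"] < end) & (peaks["end"] > start)).any())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_enhancers=0), dict(n_genes=0), dict(censor_frac=1.0),
         dict(true_hr=0.0), dict(treated_enrichment=0.0), dict(nb_dispersion=-1),
         dict(n_shared_responsive=1000), dict(signature_size=200)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sg.SimConfig(**kwargs)


class TestReference:
    def test_deterministic_under_seed(self, small_config):
        a = sd.simulate_reference(small_config)
        b = sd.simulate_reference(small_config)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.enhancers, b.enhancers)
        assert a.truth.to_json() == b.truth.to_json()

    def test_every_candidate_reachable_from_shared_enhancer(self, reference):
        # exhaustive traversal of the emitted map: 54 candidates via 14 regions
        shared = set(reference.truth.shared_enhancer_ids)
        assert len(shared) == 14
        reachable = set(
            reference.enhancers.loc[
                reference.enhancers["enhancer_id"].isin(shared), "gene"
            ]
        )
        assert set(reference.truth.candidate_genes) <= reachable
        assert len(reference.truth.candidate_genes) == 54

    def test_enhancers_disjoint_and_linked(self, reference):
        enh = reference.enhancers.drop_duplicates("enhancer_id").sort_values("start")
        assert (enh["start"].to_numpy()[1:] >= enh["end"].to_numpy()[:-1]).all()
        assert (reference.enhancers.groupby("enhancer_id").size() >= 1).all()
        assert (reference.enhancers.groupby("enhancer_id").size() <= 5).all()

    def test_truth_self_consistency(self, reference):
        reference.truth.validate()
        assert set(reference.truth.module_genes) <= set(reference.truth.candidate_genes)


class TestChip:
    def test_unknown_condition_rejected(self, small_config, small_reference):
        with pytest.raises(ValueError):
            sd.simulate_chip(small_config, small_reference, "heat-shock")

    def test_shared_enhancers_covered_by_significant_peaks(self, small_config, small_reference):
        peaks = sd.simulate_chip(small_config, small_reference, "OSM")
        sig = peaks[peaks["p_adj"] < 0.05]
        enh = small_reference.enhancers.drop_duplicates("enhancer_id").set_index("enhancer_id")
        for eid in small_reference.truth.shared_enhancer_ids:
            rec = enh.loc[eid]
            assert overlap_oracle(sig, rec["start"], rec["end"])

    def test_shared_in_both_private_in_one(self, small_config, small_reference):
        ref = small_reference
        osm = sd.simulate_chip(small_config, ref, "OSM")
        hyp = sd.simulate_chip(small_config, ref, "hypoxia")
        enh = ref.enhancers.drop_duplicates("enhancer_id").set_index("enhancer_id")
        for eid in ref.truth.shared_enhancer_ids:
            rec = enh.loc[eid]
            assert overlap_oracle(osm[osm.p_adj < 0.05], rec["start"], rec["end"])
            assert overlap_oracle(hyp[hyp.p_adj < 0.05], rec["start"], rec["end"])
        for eid in ref.truth.condition_private_ids["OSM"]:
            rec = enh.loc[eid]
            assert overlap_oracle(osm[osm.p_adj < 0.05], rec["start"], rec["end"])
            assert not overlap_oracle(hyp[hyp.p_adj < 0.05], rec["start"], rec["end"])

    def test_zero_background_gives_planted_count_only(self, small_config, small_reference):
        cfg = dataclasses.replace(small_config, n_background_peaks=0)
        peaks = sd.simulate_chip(cfg, small_reference, "hypoxia")
        planted = cfg.n_shared_responsive + cfg.n_condition_private
        assert len(peaks) == planted

    def test_deterministic(self, small_config, small_reference):
        a = sd.simulate_chip(small_config, small_reference, "OSM")
        b = sd.simulate_chip(small_config, small_reference, "OSM")
        pd.testing.assert_frame_equal(a, b)


class TestAtac:
    def test_unknown_label_rejected(self, small_config, small_reference):
        with pytest.raises(ValueError):
            sd.simulate_atac(small_config, small_reference, "mixed")

    def test_inducible_covers_all_shared(self, small_config, small_reference):
        atac = sd.simulate_atac(small_config, small_reference, "inducible")
        enh = small_reference.enhancers.drop_duplicates("enhancer_id").set_index("enhancer_id")
        for eid in small_reference.truth.shared_enhancer_ids:
            rec = enh.loc[eid]
            assert overlap_oracle(atac, rec["start"], rec["end"])

    def test_noninducible_avoids_all_shared(self, small_config, small_reference):
        atac = sd.simulate_atac(small_config, small_reference, "non-inducible")
        enh = small_reference.enhancers.drop_duplicates("enhancer_id").set_index("enhancer_id")
        for eid in small_reference.truth.shared_enhancer_ids:
            rec = enh.loc[eid]
            assert not overlap_oracle(atac, rec["start"], rec["end"])


class TestPanel:
    def test_deterministic(self, small_config, small_reference):
        a, _ = sd.simulate_cellline_panel(small_config, small_reference)
        b, _ = sd.simulate_cellline_panel(small_config, small_reference)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effect_yields_few_de_calls(self):
        calls = []
        for seed in range(3):
            cfg = sg.SimConfig(seed=seed, effect_log2fc=0.0, **SMALL)
            ref = sd.simulate_reference(cfg)
            panel, labels = sd.simulate_cellline_panel(cfg, ref)
            ind = [s for s in panel.columns if labels[s] == "inducible"]
            non = [s for s in panel.columns if labels[s] == "non-inducible"]
            de = sg.stats.differential_expression(panel, ind, non)
            calls.append(de["significant"].mean())
        assert np.mean(calls) <= 0.05

    def test_planted_log2fc_recovered(self, small_config, small_reference):
        panel, labels = sd.simulate_cellline_panel(small_config, small_reference)
        ind = [s for s in panel.columns if labels[s] == "inducible"]
        non = [s for s in panel.columns if labels[s] == "non-inducible"]
        log = sg.stats.normalize_counts(panel, "size_factors", log2=True)
        lfc = log.loc[small_reference.truth.inducible_up_genes, ind].mean(axis=1) \
            - log.loc[small_reference.truth.inducible_up_genes, non].mean(axis=1)
        assert ((lfc - small_config.effect_log2fc).abs() < 0.5).all()

    def test_sd_inflation_exceeds_gate(self):
        cfg = sg.SimConfig(seed=2, n_sd_inflated=5, **SMALL)
        ref = sd.simulate_reference(cfg)
        panel, labels = sd.simulate_cellline_panel(cfg, ref)
        log = sg.stats.normalize_counts(panel, "size_factors", log2=True)
        wobbled = ref.truth.inducible_up_genes[:5]
        ind = [s for s in panel.columns if labels[s] == "inducible"]
        assert (log.loc[wobbled, ind].std(axis=1, ddof=1) > 2).any()


class TestCohort:
    def test_no_censoring_all_events(self, small_config, small_reference):
        cfg = dataclasses.replace(small_config, censor_frac=0.0)
        _, surv = sd.simulate_bulk_cohort(cfg, small_reference)
        assert (surv["event"] == 1).all()

    def test_censor_fraction_near_target(self, small_config, small_reference):
        cfg = dataclasses.replace(small_config, n_tumors=800)
        _, surv = sd.simulate_bulk_cohort(cfg, small_reference)
        assert abs((surv["event"] == 0).mean() - cfg.censor_frac) < 0.08

    def test_null_hr_recovery(self, small_reference):
        est = []
        for seed in range(30):
            cfg = sg.SimConfig(seed=seed, true_hr=1.0, **SMALL)
            ref = sd.simulate_reference(cfg)
            _, surv = sd.simulate_bulk_cohort(cfg, ref)
            fit = sg.survival.cox_binary(surv["time"], surv["event"], surv["activation"])
            est.append(fit.hr)
        assert 0.8 <= np.median(est) <= 1.25

    def test_module_genes_coexpressed_via_latent_factor(self, default_config, reference, cohort):
        counts, _ = cohort
        log = sg.stats.normalize_counts(counts, "size_factors", log2=True)
        haz = reference.truth.hazardous_genes
        corr = np.corrcoef(log.loc[haz].to_numpy())
        off_diag = corr[np.triu_indices(len(haz), 1)]
        assert off_diag.min() > 0.5


class TestScrna:
    def test_deterministic(self, small_config, small_reference):
        a = sd.simulate_scrna(small_config, small_reference)
        b = sd.simulate_scrna(small_config, small_reference)
        np.testing.assert_array_equal(np.asarray(a.X), np.asarray(b.X))
        pd.testing.assert_frame_equal(a.obs, b.obs)

    def test_invalid_enrichment_rejected(self):
        with pytest.raises(ValueError):
            sg.SimConfig(treated_enrichment=-1.0)

    def test_forced_high_mt_cells_exactly_flagged(self, small_config, small_reference):
        adata = sd.simulate_scrna(small_config, small_reference)
        filt, report = sg.scrna.qc_filter(adata, min_genes=10)
        forced = set(adata.obs_names[adata.obs["forced_high_mt"]])
        removed = set(adata.obs_names) - set(filt.obs_names)
        # MT gate removes exactly the forced cells; percentile gate removes others
        assert forced <= removed
        assert report.removed_high_mt == len(forced)

    def test_program_enriched_in_treated(self, small_config, small_reference):
        adata = sd.simulate_scrna(small_config, small_reference)
        obs = adata.obs
        mal = (obs["cell_type"] == "epithelial") & ~obs["normal_adjacent"]
        p_t = obs.loc[mal & (obs["treatment"] == "treated"), "program"].mean()
        p_n = obs.loc[mal & (obs["treatment"] == "naive"), "program"].mean()
        assert p_t > p_n

    def test_mtx_round_trip(self, small_config, small_reference, tmp_path):
        adata = sd.simulate_scrna(small_config, small_reference)
        sd.write_mtx(adata, tmp_path / "sc")
        back = sd.read_mtx(tmp_path / "sc")
        np.testing.assert_array_equal(
            np.asarray(adata.X), np.asarray(back.X)
        )
        assert list(back.var_names) == list(adata.var_names)
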
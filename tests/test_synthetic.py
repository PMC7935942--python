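"""Ground-truth fidelity and determinism of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError
from scipy import stats

from gutlink.chem import fingerprint_from_smiles, tanimoto_similarity, tversky_similarity
from gutlink.integrate import filter_traits_by_keywords
from gutlink.synthetic import (
    METABOLITE_TEMPLATES,
    SyntheticConfig,
    simulate_compound_library,
    simulate_genetic_evidence,
    simulate_metabolomics,
    simulate_transcriptomics,
    viable_analog_parents,
)


class TestConfigValidation:
    def test_bad_proportions_name_the_field(self):
        with pytest.raises(ValidationError, match="diagnosis_split"):
            SyntheticConfig(diagnosis_split=(0.5, 0.5, 0.5))

    def test_planted_bounds(self):
        with pytest.raises(ValidationError, match="n_planted_da"):
            SyntheticConfig(n_metabolites=10, n_planted_da=11)
        with pytest.raises(ValidationError, match="n_planted_deg"):
            SyntheticConfig(n_genes=10, n_planted_deg=11)

    def test_counts_positive(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_participants=0)


class TestDeterminism:
    def test_metabolomics_tables_identical(self, small_cfg):
        t1, m1, g1 = simulate_metabolomics(small_cfg)
        t2, m2, g2 = simulate_metabolomics(small_cfg)
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(g1.da_metabolites, g2.da_metabolites)

    def test_transcriptomics_and_library_identical(self, small_cfg):
        c1, b1, _ = simulate_transcriptomics(small_cfg)
        c2, b2, _ = simulate_transcriptomics(small_cfg)
        pd.testing.assert_frame_equal(c1, c2)
        _, smiles = _smiles_table(small_cfg)
        lib1 = simulate_compound_library(smiles, small_cfg)
        lib2 = simulate_compound_library(smiles, small_cfg)
        pd.testing.assert_frame_equal(lib1[0], lib2[0])
        pd.testing.assert_frame_equal(lib1[1], lib2[1])

    def test_streams_independent_of_each_other(self, small_cfg):
        # regenerating one stage alone reproduces its output from simulate_all-time
        tables_a, _, _ = simulate_metabolomics(small_cfg)
        simulate_transcriptomics(small_cfg)
        tables_b, _, _ = simulate_metabolomics(small_cfg)
        pd.testing.assert_frame_equal(tables_a["method1"], tables_b["method1"])


def _smiles_table(cfg):
    names = list(METABOLITE_TEMPLATES)[: cfg.n_metabolites]
    ids = [f"M{i + 1:04d}" for i in range(len(names))]
    return ids, pd.DataFrame(
        {"metabolite_id": ids, "name": names, "smiles": [METABOLITE_TEMPLATES[n] for n in names]}
    )


class TestMetabolomics:
    def test_ground_truth_ids_exist_in_tables(self, small_cfg):
        tables, meta, truth = simulate_metabolomics(small_cfg)
        emitted = set().union(*(set(t.index) for t in tables.values()))
        assert set(truth.da_metabolites["metabolite_id"]) <= emitted
        assert set(meta["participant_id"]) == set(truth.participant_effects)

    def test_tables_nonnegative_and_share_samples(self, small_cfg):
        tables, meta, _ = simulate_metabolomics(small_cfg)
        for t in tables.values():
            assert (t.to_numpy() >= 0).all()
            assert list(t.columns) == list(meta["sample_id"])

    def test_null_config_has_no_group_separation(self):
        cfg = SyntheticConfig(
            n_participants=60, n_metabolites=120, n_planted_da=0, participant_sd=0, site_sd=0,
            seed=23,
        )
        empty = pd.DataFrame(columns=["metabolite_id", "disease", "log10fc"])
        tables, meta, _ = simulate_metabolomics(cfg, planted=empty)
        log_areas = np.log10(tables["method1"])
        diag = meta.set_index("sample_id")["diagnosis"]
        cd = [c for c in log_areas.columns if diag[c] == "CD"]
        non = [c for c in log_areas.columns if diag[c] == "nonIBD"]
        pvals = [
            stats.ttest_ind(log_areas.loc[m, cd], log_areas.loc[m, non]).pvalue
            for m in log_areas.index
        ]
        assert np.mean(np.asarray(pvals) >= 0.001) >= 0.99

    def test_planted_log10_ratio_recovered_at_default_conditions(self, default_bundle):
        tables = default_bundle.peak_tables
        meta = default_bundle.sample_metadata
        truth = default_bundle.truth
        stacked = pd.concat(tables.values())
        log_mean = np.log10(stacked.groupby(level=0).mean())
        diag = meta.set_index("sample_id")["diagnosis"]
        for disease in ("CD", "UC"):
            d_cols = [c for c in log_mean.columns if diag[c] == disease]
            n_cols = [c for c in log_mean.columns if diag[c] == "nonIBD"]
            sub = truth.da_metabolites[truth.da_metabolites["disease"] == disease]
            for _, row in sub.iterrows():
                emp = (
                    log_mean.loc[row["metabolite_id"], d_cols].mean()
                    - log_mean.loc[row["metabolite_id"], n_cols].mean()
                )
                assert abs(emp - row["log10fc"]) <= 0.15


class TestTranscriptomics:
    def test_counts_are_integers_and_libraries_spread(self, small_cfg):
        counts, meta, _ = simulate_transcriptomics(small_cfg)
        mat = counts.to_numpy()
        assert np.issubdtype(mat.dtype, np.integer)
        totals = mat.sum(axis=0)
        assert totals.max() / totals.min() >= 3.0

    def test_planted_fold_change_visible_in_sample_means(self):
        cfg = SyntheticConfig(n_participants=90, n_genes=400, n_planted_deg=30, seed=31)
        counts, meta, truth = simulate_transcriptomics(cfg)
        diag = meta.set_index("sample_id")["diagnosis"]
        cd = [c for c in counts.columns if diag[c] == "CD"]
        non = [c for c in counts.columns if diag[c] == "nonIBD"]
        planted_cd = truth.deg_genes[truth.deg_genes["disease"] == "CD"]
        up = planted_cd[planted_cd["log2fc"] > 0]["gene_id"]
        ratios = (counts.loc[up, cd].mean(axis=1) / counts.loc[up, non].mean(axis=1)).to_numpy()
        # planted 4-fold genes: geometric-mean ratio near 4 within +-30%
        gm = np.exp(np.mean(np.log(ratios)))
        assert 0.7 * 4 <= gm <= 1.3 * 4

    def test_sign_recovery_of_planted_genes(self, small_cfg):
        counts, meta, truth = simulate_transcriptomics(small_cfg)
        diag = meta.set_index("sample_id")["diagnosis"]
        non = [c for c in counts.columns if diag[c] == "nonIBD"]
        ok = 0
        for _, row in truth.deg_genes.iterrows():
            d = [c for c in counts.columns if diag[c] == row["disease"]]
            ratio = counts.loc[row["gene_id"], d].mean() / max(
                counts.loc[row["gene_id"], non].mean(), 1e-9
            )
            ok += (np.log2(max(ratio, 1e-9)) > 0) == (row["log2fc"] > 0)
        assert ok / len(truth.deg_genes) >= 0.95


class TestCompoundLibrary:
    def test_planted_analogs_exceed_thresholds_decoys_do_not(self, small_cfg):
        ids, smiles = _smiles_table(small_cfg)
        compounds, assays, truth = simulate_compound_library(smiles, small_cfg)
        fps = {
            r["metabolite_id"]: fingerprint_from_smiles(r["smiles"])
            for _, r in smiles.iterrows()
        }
        comp_fp = {
            r["compound_id"]: fingerprint_from_smiles(r["smiles"])
            for _, r in compounds.iterrows()
        }
        for _, pair in truth.true_pairs.iterrows():
            q, c = fps[pair["metabolite_id"]], comp_fp[pair["compound_id"]]
            assert tanimoto_similarity(q, c) >= 0.85 or tversky_similarity(q, c, 0.05) >= 0.95
        for cid in truth.decoy_compounds:
            for q in fps.values():
                assert tanimoto_similarity(q, comp_fp[cid]) < 0.85
                assert tversky_similarity(q, comp_fp[cid], 0.05) < 0.95

    def test_every_compound_has_an_assay(self, small_cfg):
        _, smiles = _smiles_table(small_cfg)
        compounds, assays, _ = simulate_compound_library(smiles, small_cfg)
        assert set(compounds["compound_id"]) == set(assays["compound_id"])
        assert assays["pxc50"].between(0, 14, inclusive="neither").all()
        assert assays["readout_type"].isin(["pIC50", "pEC50"]).all()

    def test_zero_planted_analogs_means_zero_pairs(self, small_cfg):
        cfg = small_cfg.model_copy(update={"n_planted_analogs": 0})
        _, smiles = _smiles_table(cfg)
        compounds, _, truth = simulate_compound_library(smiles, cfg)
        assert truth.true_pairs.empty
        fps = {r["metabolite_id"]: fingerprint_from_smiles(r["smiles"]) for _, r in smiles.iterrows()}
        for _, r in compounds.iterrows():
            c = fingerprint_from_smiles(r["smiles"])
            assert all(
                tanimoto_similarity(q, c) < 0.85 and tversky_similarity(q, c, 0.05) < 0.95
                for q in fps.values()
            )

    def test_unparsable_smiles_reported(self, small_cfg):
        bad = pd.DataFrame(
            {"metabolite_id": ["MX"], "name": ["bogus"], "smiles": ["this_is_not_smiles"]}
        )
        from gutlink.chem import SmilesParseError

        with pytest.raises(SmilesParseError, match="this_is_not_smiles"):
            viable_analog_parents(bad)


class TestGeneticEvidence:
    def test_planted_traits_pass_keyword_filter(self, small_cfg):
        targets = [f"T{i:04d}" for i in range(1, 21)]
        evidence, truth = simulate_genetic_evidence(targets, small_cfg)
        retained = filter_traits_by_keywords(evidence)
        assert set(truth.evidence_targets) <= set(retained["gene_id"])
        # unrelated traits are excluded
        unrelated = evidence[~evidence["gene_id"].isin(truth.evidence_targets)]
        assert not set(unrelated["gene_id"]) & set(retained["gene_id"])

    def test_empty_target_list_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            simulate_genetic_evidence([], small_cfg)

    def test_empty_keywords_retain_nothing_uncurated(self, small_cfg):
        targets = [f"T{i:04d}" for i in range(1, 11)]
        evidence, _ = simulate_genetic_evidence(targets, small_cfg)
        assert filter_traits_by_keywords(evidence, keywords=[]).empty
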
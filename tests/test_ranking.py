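"""Model zoo, grid search, mixed-effects boosting, importances, consensus."""

import warnings

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from gutlink.metabolomics import AbundanceMatrix
from gutlink.ranking import (
    DEFAULT_GRID,
    MixedEffectsGBM,
    build_features,
    compute_consensus,
    evaluate_model_zoo,
    extract_importances,
    fit_gbm_with_grid,
    participant_holdout_split,
    scale_consensus,
    select_top_quartile,
)


def separable_dataset(seed=0, n_participants=45, per=3, n_feats=12, shuffle_labels=False):
    """Three diagnosis classes cleanly separated along two features."""
    rng = np.random.default_rng(seed)
    diag = np.repeat(["CD", "UC", "nonIBD"], n_participants // 3)
    rows, meta = [], []
    for i, d in enumerate(diag):
        pid = f"P{i:03d}"
        center = {"CD": (4, 0), "UC": (0, 4), "nonIBD": (0, 0)}[d]
        for t in range(per):
            feats = rng.normal(size=n_feats)
            feats[0] += center[0]
            feats[1] += center[1]
            rows.append(feats)
            meta.append(
                {
                    "sample_id": f"S{len(meta):04d}",
                    "participant_id": pid,
                    "diagnosis": d,
                    "site": f"Site{i % 3}",
                    "age": 40,
                    "sex": "F",
                    "antibiotics": False,
                    "timepoint": t + 1,
                }
            )
    meta = pd.DataFrame(meta)
    if shuffle_labels:
        shuffled = meta[["participant_id", "diagnosis"]].drop_duplicates()
        rng2 = np.random.default_rng(seed + 1)
        new = dict(zip(shuffled["participant_id"], rng2.permutation(shuffled["diagnosis"])))
        meta["diagnosis"] = meta["participant_id"].map(new)
    values = pd.DataFrame(
        np.array(rows).T, index=[f"M{i:03d}" for i in range(n_feats)], columns=meta["sample_id"]
    )
    return AbundanceMatrix(values, "clr", 1e-6), meta


class TestHoldoutSplit:
    def test_participant_disjoint_and_stratified(self):
        _, meta = separable_dataset()
        train, test = participant_holdout_split(meta, 0.15, seed=3)
        train_p = set(meta.loc[train, "participant_id"])
        test_p = set(meta.loc[test, "participant_id"])
        assert not train_p & test_p
        for d in ("CD", "UC", "nonIBD"):
            assert (meta.loc[test, "diagnosis"] == d).any()


class TestModelZoo:
    def test_separable_classes_score_high(self):
        matrix, meta = separable_dataset(seed=5)
        scores = evaluate_model_zoo(matrix, meta, seed=5)
        assert len(scores) == 8
        assert scores[0].weighted_f1 >= 0.95

    def test_shuffled_labels_score_low(self):
        matrix, meta = separable_dataset(seed=6, shuffle_labels=True)
        scores = evaluate_model_zoo(matrix, meta, seed=6)
        assert scores[0].weighted_f1 <= 0.55

    def test_same_seed_same_ranking(self):
        matrix, meta = separable_dataset(seed=7)
        a = [s.model_name for s in evaluate_model_zoo(matrix, meta, seed=7)]
        b = [s.model_name for s in evaluate_model_zoo(matrix, meta, seed=7)]
        assert a == b


class TestGridSearch:
    def test_empty_grid_rejected(self):
        matrix, meta = separable_dataset()
        with pytest.raises(ValueError, match="empty"):
            fit_gbm_with_grid(matrix, meta, grid={}, seed=0)
        with pytest.raises(ValueError, match="empty"):
            fit_gbm_with_grid(matrix, meta, grid={"max_depth": []}, seed=0)

    def test_single_point_grid_equals_direct_fit(self):
        matrix, meta = separable_dataset(seed=8)
        grid = {"max_depth": [3], "n_estimators": [50], "learning_rate": [0.3]}
        model, best = fit_gbm_with_grid(matrix, meta, grid=grid, seed=8)
        assert best == {"max_depth": 3, "n_estimators": 50, "learning_rate": 0.3}
        x, y, _ = build_features(matrix, meta)
        direct = xgb.XGBClassifier(
            tree_method="hist", n_jobs=1, random_state=8, **best
        ).fit(x, pd.Categorical(y).codes)
        assert np.array_equal(model.predict(x), direct.predict(x))

    def test_depth_structured_data_selects_deeper_trees(self):
        # XOR of three feature signs requires interactions deeper than 2
        rng = np.random.default_rng(0)
        n = 600
        x = rng.normal(size=(n, 8))
        y = (x[:, 0] > 0).astype(int) ^ (x[:, 1] > 0).astype(int) ^ (x[:, 2] > 0).astype(int)
        meta = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "participant_id": [f"P{i}" for i in range(n)],
                "diagnosis": np.where(y == 1, "CD", "nonIBD"),
                "site": "Site0",
                "age": 40,
                "sex": "F",
                "antibiotics": False,
                "timepoint": 1,
            }
        )
        matrix = AbundanceMatrix(
            pd.DataFrame(x.T, index=[f"M{i}" for i in range(8)], columns=meta["sample_id"]),
            "clr",
            1e-6,
        )
        grid = {"max_depth": [2, 4], "n_estimators": [50], "learning_rate": [0.3]}
        _, best = fit_gbm_with_grid(matrix, meta, grid=grid, seed=0)
        assert best["max_depth"] == 4

    def test_deterministic_under_seed(self):
        matrix, meta = separable_dataset(seed=9)
        grid = {"max_depth": [2, 3], "n_estimators": [30], "learning_rate": [0.3]}
        _, b1 = fit_gbm_with_grid(matrix, meta, grid=grid, seed=9)
        _, b2 = fit_gbm_with_grid(matrix, meta, grid=grid, seed=9)
        assert b1 == b2


def clustered_binary(sd, seed, n_clusters=50, per=20, n_feat=10):
    rng = np.random.default_rng(seed)
    n = n_clusters * per
    X = pd.DataFrame(rng.normal(size=(n, n_feat)), columns=[f"f{i}" for i in range(n_feat)])
    b = rng.normal(0, sd, n_clusters) if sd > 0 else np.zeros(n_clusters)
    clusters = np.repeat(np.arange(n_clusters), per)
    eta = 0.8 * X["f0"].to_numpy() - 0.5 * X["f1"].to_numpy() + b[clusters]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y, clusters


class TestMixedEffectsGBM:
    def test_null_data_shrinks_sigma(self):
        X, y, cl = clustered_binary(0.0, seed=42)
        me = MixedEffectsGBM(seed=0, use_site=False).fit(X, y, clusters=cl)
        assert me.sigma_b <= 0.1

    def test_planted_intercepts_recovered(self):
        X, y, cl = clustered_binary(1.0, seed=42)
        me = MixedEffectsGBM(seed=0, use_site=False).fit(X, y, clusters=cl)
        assert 0.5 <= me.sigma_b <= 2.0

    def test_intercepts_centered(self):
        X, y, cl = clustered_binary(1.0, seed=11)
        me = MixedEffectsGBM(seed=0, use_site=False).fit(X, y, clusters=cl)
        for cls in me.classes_:
            b = np.array(list(me.random_intercepts_[cls]["participant"].values()))
            assert abs(b.mean()) <= 0.05

    def test_zeroed_intercepts_equal_fixed_learner(self):
        X, y, cl = clustered_binary(1.0, seed=12, n_clusters=10, per=10)
        me = MixedEffectsGBM(seed=0, use_site=False).fit(X, y, clusters=cl)
        margins_no_b = me._margins(X, clusters=None)
        for k, cls in enumerate(me.classes_):
            fixed = me.models_[cls].predict(X, output_margin=True, base_margin=np.zeros(len(X)))
            assert np.allclose(margins_no_b[:, k], fixed)

    def test_single_cluster_degenerates(self):
        X, y, _ = clustered_binary(0.0, seed=13, n_clusters=1, per=60)
        me = MixedEffectsGBM(seed=0, use_site=False).fit(X, y, clusters=np.zeros(60, dtype=int))
        assert me.degenerate_ and me.sigma_b == 0.0


class TestImportances:
    @pytest.fixture(scope="class")
    def fitted(self):
        matrix, meta = separable_dataset(seed=20)
        grid = {"max_depth": [3], "n_estimators": [60], "learning_rate": [0.3]}
        model, _ = fit_gbm_with_grid(matrix, meta, grid=grid, seed=20)
        x, y, m = build_features(matrix, meta)
        return model, x, list(matrix.values.index)

    def test_informative_features_dominate(self, fitted):
        model, x, mets = fitted
        imp = extract_importances(model, x, "CD", mets)
        # M000/M001 carry all the signal
        top = imp["gain"].sort_values(ascending=False).index[:2]
        assert set(top) == {"M000", "M001"}

    def test_metadata_excluded_from_vectors(self, fitted):
        model, x, mets = fitted
        imp = extract_importances(model, x, "CD", mets)
        for vec in imp.values():
            assert "age" not in vec.index and "site_code" not in vec.index

    def test_shap_additivity(self, fitted):
        model, x, mets = fitted
        booster = model.get_booster()
        dm = xgb.DMatrix(x)
        contribs = booster.predict(dm, pred_contribs=True)
        margins = booster.predict(dm, output_margin=True)
        assert np.allclose(contribs.sum(axis=-1), margins, atol=1e-4)

    def test_unfitted_model_rejected(self, fitted):
        _, x, mets = fitted
        with pytest.raises(ValueError, match="not fitted"):
            extract_importances(MixedEffectsGBM(), x, "CD", mets)


def _importance_inputs(values: dict[str, list[float]], mets):
    """Build per-disease importance dicts from raw component vectors."""
    out = {}
    for d in ("CD", "UC"):
        out[d] = {
            "gain": pd.Series(values["gain"], index=mets),
            "importance": pd.Series(values["importance"], index=mets),
            "shap": pd.Series(values["shap"], index=mets),
        }
    return out


def _da_table(mets, qs):
    rows = []
    for contrast in ("CD_vs_nonIBD", "UC_vs_nonIBD"):
        for m, q in zip(mets, qs):
            rows.append({"metabolite_id": m, "contrast": contrast, "q_value": q})
    return pd.DataFrame(rows)


class TestConsensus:
    def test_scale_consensus_worked_example(self):
        got = scale_consensus([0.2, 0.45, 0.8])
        assert np.allclose(got, [0.0, 0.6455, 1.0], atol=1e-4)

    def test_sqrt_preserves_ranking(self):
        rng = np.random.default_rng(21)
        raw = rng.uniform(size=50)
        scaled = scale_consensus(raw)
        assert np.array_equal(np.argsort(raw), np.argsort(scaled))

    def test_extreme_metabolites(self):
        mets = ["A", "B", "C"]
        imps = _importance_inputs(
            {"gain": [9, 1, 0], "importance": [5, 2, 0], "shap": [3, 1, 0]}, mets
        )
        da = _da_table(mets, [1e-8, 0.2, 1.0])
        table = compute_consensus(da, imps, imps)
        byid = table[table["disease"] == "CD"].set_index("metabolite_id")
        assert byid.loc["A", "consensus"] == pytest.approx(1.0)
        assert byid.loc["C", "consensus"] == pytest.approx(0.0)

    def test_affine_component_rescaling_is_absorbed(self):
        mets = ["A", "B", "C", "D"]
        base = {"gain": [4.0, 3, 2, 1], "importance": [1.0, 2, 3, 4], "shap": [2.0, 1, 4, 3]}
        da = _da_table(mets, [0.01, 0.2, 0.5, 0.9])
        t1 = compute_consensus(da, _importance_inputs(base, mets), _importance_inputs(base, mets))
        scaled = {k: [7 * v + 2 for v in vals] for k, vals in base.items()}
        t2 = compute_consensus(da, _importance_inputs(scaled, mets), _importance_inputs(scaled, mets))
        pd.testing.assert_frame_equal(t1, t2)

    def test_component_monotonicity(self):
        mets = ["A", "B", "C"]
        base = {"gain": [1.0, 2, 3], "importance": [1.0, 2, 3], "shap": [1.0, 2, 3]}
        da = _da_table(mets, [0.5, 0.5, 0.5])
        t1 = compute_consensus(da, _importance_inputs(base, mets), _importance_inputs(base, mets))
        boosted = {**base, "gain": [2.5, 2, 3]}  # raise A's gain only
        t2 = compute_consensus(da, _importance_inputs(boosted, mets), _importance_inputs(base, mets))
        r1 = t1[t1["disease"] == "CD"].set_index("metabolite_id")["consensus"].rank()
        r2 = t2[t2["disease"] == "CD"].set_index("metabolite_id")["consensus"].rank()
        assert r2["A"] >= r1["A"]

    def test_missing_component_raises(self):
        mets = ["A", "B"]
        imps = _importance_inputs({"gain": [1, 2], "importance": [1, 2], "shap": [1, 2]}, mets)
        da = _da_table(["A"], [0.5])  # B missing
        with pytest.raises(ValueError, match="B"):
            compute_consensus(da, imps, imps)

    def test_top_quartile_selection(self):
        mets = [f"M{i}" for i in range(8)]
        imps = _importance_inputs(
            {"gain": list(range(8)), "importance": list(range(8)), "shap": list(range(8))}, mets
        )
        da = _da_table(mets, np.linspace(0.9, 0.01, 8))
        table = compute_consensus(da, imps, imps)
        per_disease = table[table["disease"] == "CD"]
        assert per_disease["top_quartile"].sum() == 2
        assert select_top_quartile(table) == {"M6", "M7"}

    def test_all_tied_scores_select_everything(self):
        mets = ["A", "B", "C"]
        imps = _importance_inputs({"gain": [1, 1, 1], "importance": [1, 1, 1], "shap": [1, 1, 1]}, mets)
        da = _da_table(mets, [0.5, 0.5, 0.5])
        table = compute_consensus(da, imps, imps)
        assert table["top_quartile"].all()
        assert select_top_quartile(table) == set(mets)
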
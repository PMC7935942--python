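"""Consensus ranking of metabolites from classifier feature attributions.

Diagnosis (CD / UC / nonIBD) is predicted from the transformed metabolite
matrix plus recruitment site, antibiotics use and age. A zoo of standard
classifiers is scored by weighted F1 on a participant-disjoint holdout for
reporting; the consensus itself always combines six per-metabolite
components:

  s1  scaled significance, -log10 of the BH-adjusted Mann-Whitney q value
  s2  split gain in the grid-tuned gradient-boosting model
  s3  split count ("weight" importance) in the tuned model
  s4  mean |SHAP| for the disease class in the tuned model
  s5  feature importance in the mixed-effects gradient-boosting model
  s6  mean |SHAP| for the disease class in the mixed-effects model

Each component is min-max scaled over metabolites, averaged, min-max scaled
again over all (metabolite, disease) rows and square-root normalized. The
top quartile per disease state (union across states) is the candidate set.

SHAP attributions are computed with XGBoost's native TreeSHAP
(``pred_contribs``). The mixed-effects model alternates a boosted-trees fit
with shrinkage re-estimation of per-participant and per-site random
intercepts on the logit scale (a GMERF-style penalized quasi-likelihood
alternation), one-vs-rest per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .metabolomics import AbundanceMatrix

__all__ = [
    "ModelScore",
    "MixedEffectsGBM",
    "build_features",
    "participant_holdout_split",
    "evaluate_model_zoo",
    "fit_gbm_with_grid",
    "extract_importances",
    "compute_consensus",
    "select_top_quartile",
]

DEFAULT_GRID = {
    "max_depth": [2, 4, 6],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [100, 300],
}
METADATA_FEATURES = ("site_code", "antibiotics", "age", "sex_code")
Q_CAP = 1e-10


@dataclass
class ModelScore:
    model_name: str
    weighted_f1: float
    cv_folds: int = 10
    holdout_fraction: float = 0.15


def build_features(
    matrix: AbundanceMatrix, metadata: pd.DataFrame, include_sex: bool = False
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Sample-by-feature matrix (metabolites + site/antibiotics/age), labels, metadata."""
    meta = metadata.set_index("sample_id")
    samples = [s for s in matrix.values.columns if s in meta.index]
    x = matrix.values[samples].T.copy()
    meta = meta.loc[samples]
    x["site_code"] = pd.Categorical(meta["site"]).codes.astype(float)
    x["antibiotics"] = meta["antibiotics"].astype(float).to_numpy()
    x["age"] = meta["age"].astype(float).to_numpy()
    if include_sex:
        x["sex_code"] = (meta["sex"] == "M").astype(float).to_numpy()
    y = meta["diagnosis"].astype(str)
    return x, y, meta.reset_index()


def participant_holdout_split(
    metadata: pd.DataFrame, holdout_fraction: float = 0.15, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (train, holdout) sample masks, participant-disjoint, stratified by diagnosis."""
    rng = np.random.default_rng(seed)
    participants = metadata[["participant_id", "diagnosis"]].drop_duplicates()
    holdout_parts: set[str] = set()
    for _, grp in participants.groupby("diagnosis"):
        ids = grp["participant_id"].to_numpy().copy()
        rng.shuffle(ids)
        k = max(1, int(round(holdout_fraction * len(ids))))
        holdout_parts.update(ids[:k])
    test = metadata["participant_id"].isin(holdout_parts).to_numpy()
    return ~test, test


class MixedEffectsGBM:
    """Gradient boosting with per-cluster random intercepts (one-vs-rest).

    For each class, alternates (a) fitting an XGBoost binary classifier with
    the current random intercepts supplied as base margin and (b) shrinkage
    re-estimation of per-participant and per-site intercepts and their SDs
    from the working residuals of the penalized quasi-likelihood
    linearization. Stops when the largest intercept change falls below
    ``tol`` or after ``max_iters`` alternations.
    """

    def __init__(
        self,
        max_iters: int = 20,
        tol: float = 1e-3,
        seed: int = 0,
        use_participant: bool = True,
        use_site: bool = True,
        xgb_params: dict | None = None,
    ):
        self.max_iters = max_iters
        self.tol = tol
        self.seed = seed
        self.use_participant = use_participant
        self.use_site = use_site
        self.xgb_params = {
            "n_estimators": 100,
            "max_depth": 3,
            "learning_rate": 0.1,
            "min_child_weight": 5,
            "tree_method": "hist",
            "n_jobs": 1,
        }
        if xgb_params:
            self.xgb_params.update(xgb_params)

    # -- internal: one grouping's shrinkage update ---------------------------
    @staticmethod
    def _update_intercepts(resid, weights, codes, n_groups, sigma2):
        """Moment estimate of the intercept variance, then BLUP shrinkage.

        sigma^2 is estimated as the between-cluster variance of the weighted
        working-residual means minus their average conditional variance
        (truncated at zero), so null data contracts to zero in one step;
        intercepts are the usual normal-model posterior means.
        """
        sw = np.bincount(codes, weights=weights, minlength=n_groups)
        swr = np.bincount(codes, weights=weights * resid, minlength=n_groups)
        ok = sw > 0
        means = np.zeros(n_groups)
        means[ok] = swr[ok] / sw[ok]
        cond_var = np.zeros(n_groups)
        cond_var[ok] = 1.0 / sw[ok]
        if ok.sum() >= 2:
            sigma2_new = max(0.0, float(np.var(means[ok], ddof=1) - cond_var[ok].mean()))
        else:
            sigma2_new = 0.0
        shrink = sigma2_new / (sigma2_new + cond_var + 1e-12)
        b = shrink * means
        return b, sigma2_new

    def fit(self, X: pd.DataFrame, y, clusters, sites=None):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        clusters = pd.Categorical(np.asarray(clusters))
        self._cluster_categories = list(clusters.categories)
        codes_p = clusters.codes.astype(int)
        n_p = len(clusters.categories)
        if sites is not None and self.use_site:
            site_cat = pd.Categorical(np.asarray(sites))
            self._site_categories = list(site_cat.categories)
            codes_s = site_cat.codes.astype(int)
            n_s = len(site_cat.categories)
        else:
            self._site_categories = []
            codes_s, n_s = None, 0

        self.models_: dict = {}
        self.random_intercepts_: dict = {}
        self.sigma_b_: dict = {}
        self.converged_: dict = {}
        self.degenerate_ = n_p < 2
        n = len(y)

        for cls in self.classes_:
            yb = (y == cls).astype(int)
            b_p = np.zeros(n_p)
            b_s = np.zeros(n_s) if n_s else None
            s2_p, s2_s = 1.0, 1.0
            converged = False
            clf = None
            for _ in range(self.max_iters):
                offset = b_p[codes_p] if self.use_participant and not self.degenerate_ else np.zeros(n)
                if b_s is not None:
                    offset = offset + b_s[codes_s]
                clf = xgb.XGBClassifier(random_state=self.seed, **self.xgb_params)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X, yb, base_margin=offset)
                fixed = clf.predict(X, output_margin=True, base_margin=np.zeros(n))
                eta = fixed + offset
                p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
                w = np.clip(p * (1 - p), 1e-3, None)
                resid = np.clip(offset + (yb - p) / w, -10, 10)
                delta = 0.0
                if self.use_participant and not self.degenerate_:
                    other = b_s[codes_s] if b_s is not None else 0.0
                    new_bp, s2_p = self._update_intercepts(resid - other, w, codes_p, n_p, s2_p)
                    shift = new_bp.mean()
                    new_bp = new_bp - shift  # keep intercepts centered
                    delta = max(delta, float(np.max(np.abs(new_bp - b_p))))
                    b_p = new_bp
                if b_s is not None:
                    other = b_p[codes_p] if self.use_participant and not self.degenerate_ else 0.0
                    new_bs, s2_s = self._update_intercepts(resid - other, w, codes_s, n_s, s2_s)
                    new_bs = new_bs - new_bs.mean()
                    delta = max(delta, float(np.max(np.abs(new_bs - b_s))))
                    b_s = new_bs
                if delta < self.tol:
                    converged = True
                    break
            self.models_[cls] = clf
            self.random_intercepts_[cls] = {
                "participant": dict(zip(self._cluster_categories, b_p)),
                "site": dict(zip(self._site_categories, b_s)) if b_s is not None else {},
            }
            self.sigma_b_[cls] = {
                "participant": 0.0 if self.degenerate_ else float(np.sqrt(s2_p)),
                "site": float(np.sqrt(s2_s)) if b_s is not None else 0.0,
            }
            self.converged_[cls] = converged
        return self

    @property
    def sigma_b(self) -> float:
        """Participant-level random-intercept SD, averaged over class models."""
        return float(np.mean([v["participant"] for v in self.sigma_b_.values()]))

    @property
    def converged(self) -> bool:
        return all(self.converged_.values())

    def _margins(self, X, clusters=None, sites=None) -> np.ndarray:
        X = pd.DataFrame(X)
        n = len(X)
        cols = []
        for cls in self.classes_:
            offset = np.zeros(n)
            if clusters is not None:
                bmap = self.random_intercepts_[cls]["participant"]
                offset += np.array([bmap.get(c, 0.0) for c in np.asarray(clusters)])
            if sites is not None:
                smap = self.random_intercepts_[cls]["site"]
                offset += np.array([smap.get(s, 0.0) for s in np.asarray(sites)])
            m = self.models_[cls].predict(X, output_margin=True, base_margin=np.zeros(n))
            cols.append(m + offset)
        return np.column_stack(cols)

    def predict_proba(self, X, clusters=None, sites=None) -> np.ndarray:
        m = self._margins(X, clusters, sites)
        p = 1.0 / (1.0 + np.exp(-np.clip(m, -30, 30)))
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X, clusters=None, sites=None):
        return self.classes_[np.argmax(self._margins(X, clusters, sites), axis=1)]


def _zoo(seed: int) -> dict:
    return {
        "logistic_regression": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier()),
        "random_forest": RandomForestClassifier(random_state=seed),
        "dense_net": make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64, 32, 16), max_iter=300, random_state=seed),
        ),
        "gaussian_nb": GaussianNB(),
        "linear_ovr": make_pipeline(
            StandardScaler(), OneVsRestClassifier(LinearSVC(random_state=seed))
        ),
        "xgboost": xgb.XGBClassifier(tree_method="hist", n_jobs=1, random_state=seed),
    }


def evaluate_model_zoo(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    seed: int = 0,
    holdout_fraction: float = 0.15,
) -> list[ModelScore]:
    """Holdout weighted-F1 scores for the classifier zoo, sorted descending.

    The holdout split is participant-disjoint (repeated samples of one
    participant never straddle the split) and stratified by diagnosis.
    """
    x, y, meta = build_features(matrix, metadata)
    train, test = participant_holdout_split(meta, holdout_fraction, seed)
    y_codes = pd.Categorical(y)
    y_num = pd.Series(y_codes.codes, index=y.index)
    if len(np.unique(y_num[train])) < len(y_codes.categories):
        raise ValueError("a diagnosis class is absent from the training split")
    scores = []
    for name, model in _zoo(seed).items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x[train], y_num[train])
            pred = model.predict(x[test])
        scores.append(
            ModelScore(name, float(f1_score(y_num[test], pred, average="weighted")),
                       holdout_fraction=holdout_fraction)
        )
    me = MixedEffectsGBM(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        me.fit(
            x[train],
            y_num[train],
            clusters=meta.loc[train, "participant_id"],
            sites=meta.loc[train, "site"],
        )
    pred = me.predict(
        x[test], clusters=meta.loc[test, "participant_id"], sites=meta.loc[test, "site"]
    )
    scores.append(
        ModelScore(
            "mixed_effects_xgboost",
            float(f1_score(y_num[test], pred, average="weighted")),
            holdout_fraction=holdout_fraction,
        )
    )
    return sorted(scores, key=lambda s: -s.weighted_f1)


def fit_gbm_with_grid(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    grid: dict | None = None,
    seed: int = 0,
) -> tuple[xgb.XGBClassifier, dict]:
    """Exhaustive 5-fold grid search over XGBoost hyperparameters.

    Refits on the full training data with the best parameters; returns the
    fitted classifier and the chosen grid point.
    """
    grid = DEFAULT_GRID if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid is empty")
    x, y, _ = build_features(matrix, metadata)
    y_num = pd.Categorical(y).codes
    base = xgb.XGBClassifier(tree_method="hist", n_jobs=1, random_state=seed)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, cv=cv, scoring="f1_weighted", n_jobs=1, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(x, y_num)
    model = search.best_estimator_
    model._label_categories = list(pd.Categorical(y).categories)
    return model, dict(search.best_params_)


def _booster_scores(booster: xgb.Booster, feature_names: list[str], kind: str) -> pd.Series:
    raw = booster.get_score(importance_type=kind)
    out = pd.Series(0.0, index=feature_names)
    for k, v in raw.items():
        # keys are feature names when the model was fit on a DataFrame
        if k in out.index:
            out[k] = v
        elif k.startswith("f") and k[1:].isdigit():
            out.iloc[int(k[1:])] = v
    return out


def _shap_mean_abs(booster, X: pd.DataFrame, class_idx: int, n_classes: int) -> pd.Series:
    dm = xgb.DMatrix(X)
    contribs = booster.predict(dm, pred_contribs=True)
    if contribs.ndim == 3:  # multiclass: (n, n_class, n_feat+1)
        contribs = contribs[:, class_idx, :]
    mean_abs = np.abs(contribs[:, :-1]).mean(axis=0)  # drop bias column
    return pd.Series(mean_abs, index=list(X.columns))


def extract_importances(
    model, X: pd.DataFrame, disease: str, metabolite_ids: list[str]
) -> dict[str, pd.Series]:
    """Gain, split-count importance and mean |SHAP| per metabolite.

    Metadata covariates stay in the model but are excluded from the returned
    metabolite vectors. ``disease`` selects the SHAP class (the class index
    of the tuned multiclass model, or the class-specific binary model of the
    mixed-effects ensemble).
    """
    feature_names = list(X.columns)
    if isinstance(model, MixedEffectsGBM):
        if not hasattr(model, "models_"):
            raise ValueError("model is not fitted")
        label = _resolve_class(model.classes_, disease)
        booster = model.models_[label].get_booster()
        gain = sum(
            _booster_scores(m.get_booster(), feature_names, "total_gain")
            for m in model.models_.values()
        ) / len(model.models_)
        weight = sum(
            _booster_scores(m.get_booster(), feature_names, "weight")
            for m in model.models_.values()
        ) / len(model.models_)
        shap_vals = _shap_mean_abs(booster, X, 0, 2)
    else:
        if not hasattr(model, "classes_"):
            raise ValueError("model is not fitted")
        booster = model.get_booster()
        labels = getattr(model, "_label_categories", list(model.classes_))
        class_idx = labels.index(disease) if disease in labels else int(disease)
        gain = _booster_scores(booster, feature_names, "total_gain")
        weight = _booster_scores(booster, feature_names, "weight")
        shap_vals = _shap_mean_abs(booster, X, class_idx, len(labels))
    keep = [m for m in metabolite_ids if m in feature_names]
    return {
        "gain": gain.reindex(keep).fillna(0.0),
        "importance": weight.reindex(keep).fillna(0.0),
        "shap": shap_vals.reindex(keep).fillna(0.0),
    }


def _resolve_class(classes, disease):
    if disease in classes:
        return disease
    # numeric-coded labels: caller maps disease to the numeric label
    raise KeyError(f"class {disease!r} not in model classes {list(classes)}")


def _minmax(s: pd.Series, degenerate: float = 0.5) -> pd.Series:
    lo, hi = float(s.min()), float(s.max())
    if hi - lo <= 0:
        return pd.Series(degenerate, index=s.index)
    return (s - lo) / (hi - lo)


def scale_consensus(raw_means) -> np.ndarray:
    """Min-max rescale the component averages over all rows, then square root.

    The final normalization of the consensus score; all-equal input maps to 1
    (every row is simultaneously the maximum).
    """
    s = pd.Series(np.asarray(raw_means, dtype=float))
    return np.sqrt(_minmax(s, degenerate=1.0).to_numpy())


def compute_consensus(
    da: pd.DataFrame,
    tuned_importances: dict[str, dict[str, pd.Series]],
    me_importances: dict[str, dict[str, pd.Series]],
    quartile: float = 0.75,
) -> pd.DataFrame:
    """Six-component consensus table per (metabolite, disease state).

    ``da`` is the differential-abundance result table; importances are keyed
    by disease ("CD", "UC") then component source. Component s1 uses
    -log10(q) capped at q = 1e-10 so that smaller q means higher importance.
    """
    contrast_of = {"CD": "CD_vs_nonIBD", "UC": "UC_vs_nonIBD"}
    frames = []
    for disease in ("CD", "UC"):
        tuned = tuned_importances[disease]
        me = me_importances[disease]
        mets = list(tuned["gain"].index)
        sub = da[da["contrast"] == contrast_of[disease]].set_index("metabolite_id")
        missing = [m for m in mets if m not in sub.index]
        if missing:
            raise ValueError(f"missing q_value for metabolite(s) {missing[:5]} ({disease})")
        for comp, series in (("s2", tuned["gain"]), ("s3", tuned["importance"]),
                             ("s4", tuned["shap"]), ("s5", me["importance"]), ("s6", me["shap"])):
            if series.isna().any():
                raise ValueError(f"missing component {comp} for {disease}")
        q = sub.loc[mets, "q_value"].astype(float).clip(lower=Q_CAP)
        df = pd.DataFrame(
            {
                "metabolite_id": mets,
                "disease": disease,
                "s1": _minmax(-np.log10(q)).to_numpy(),
                "s2": _minmax(tuned["gain"]).to_numpy(),
                "s3": _minmax(tuned["importance"]).to_numpy(),
                "s4": _minmax(tuned["shap"]).to_numpy(),
                "s5": _minmax(me["importance"]).to_numpy(),
                "s6": _minmax(me["shap"]).to_numpy(),
            }
        )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table["raw_mean"] = table[["s1", "s2", "s3", "s4", "s5", "s6"]].mean(axis=1)
    table["consensus"] = scale_consensus(table["raw_mean"])
    table["top_quartile"] = False
    for disease in ("CD", "UC"):
        mask = table["disease"] == disease
        threshold = float(np.quantile(table.loc[mask, "consensus"], quartile))
        table.loc[mask, "top_quartile"] = table.loc[mask, "consensus"] >= threshold
    return table


def select_top_quartile(table: pd.DataFrame) -> set[str]:
    """Union of per-disease top-quartile metabolites (ties included)."""
    if table.empty:
        raise ValueError("consensus table is empty")
    return set(table.loc[table["top_quartile"], "metabolite_id"])
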
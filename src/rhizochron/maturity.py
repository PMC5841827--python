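"""Sparse random-forest models of microbiota age and developmental stage.

The core estimator regresses plant age (or the 1–27 developmental stage)
on OTU relative abundances with a random forest, ranks OTUs by
permutation importance (mean increase in squared prediction error when
one OTU's values are permuted), prunes the feature set by 10-fold
cross-validated elimination over a halving schedule, and refits a sparse
forest on the retained age-discriminant OTUs.  Predictions from such a
model are a sample's "microbiota age": values below the plant's true age
indicate an immature microbiota.

Training uses a stratified half split within each time point ×
compartment cell, mirroring a field design where half of every cell is
held out for validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import OtuTable, PER_MILLE

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    strata: list
    seed: int


def split_train_test(metadata: pd.DataFrame,
                     compartments=("rhizosphere", "endosphere"),
                     seed: int = 0) -> SplitPlan:
    """Stratified random half split within each time point × compartment.

    Each stratum contributes ceil(n/2) training samples; odd strata put
    the extra sample in the training half.
    """
    md = metadata[metadata["compartment"].isin(compartments)]
    if md.empty:
        raise ValueError("no samples in the requested compartments")
    rng = np.random.default_rng(seed)
    train, test, strata = [], [], []
    for (age, comp), sub in sorted(
            md.groupby(["age_days", "compartment"], observed=True),
            key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ids = sorted(sub["sample_id"])
        if not ids:
            raise ValueError(f"empty stratum {(age, comp)}")
        perm = rng.permutation(len(ids))
        n_train = int(np.ceil(len(ids) / 2))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
        strata.append((float(age), str(comp)))
    return SplitPlan(train_ids=train, test_ids=test, strata=strata, seed=seed)


def permutation_importance_mse(forest, X, y, n_repeats: int = 1,
                               seed: int = 0) -> np.ndarray:
    """Out-of-bag permutation importance: mean increase in squared error.

    For every tree, each feature's values are permuted among that tree's
    out-of-bag samples and the rise in the tree's OOB MSE is recorded;
    importances average these rises over trees.  Features a tree never
    splits on contribute exactly zero for that tree, which keeps the
    computation cheap even for thousands of OTUs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    for est, sampled in zip(forest.estimators_,
                            forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled)
        if len(oob) < 2:
            continue
        xo, yo = X[oob], y[oob]
        base = np.mean((est.predict(xo) - yo) ** 2)
        used = np.unique(est.tree_.feature[est.tree_.feature >= 0])
        for _ in range(n_repeats):
            xb = np.broadcast_to(xo, (len(used), len(oob), p)).copy()
            for bi, j in enumerate(used):
                xb[bi, :, j] = xo[rng.permutation(len(oob)), j]
            pred = est.predict(xb.reshape(-1, p)).reshape(len(used), -1)
            imp[used] += (((pred - yo) ** 2).mean(axis=1) - base) / n_repeats
    return imp / len(forest.estimators_)


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class SparseRandomForestRegressor(BaseEstimator, RegressorMixin):
    """Random-forest regressor with importance-ranked feature elimination.

    Fitting runs three stages: a full forest over all features with
    permutation importance; 10-fold cross-validated elimination over a
    halving schedule of feature-subset sizes; and a sparse refit on the
    selected subset.  ``n_select`` overrides the automatic subset choice
    (smallest size whose CV error is within ``tolerance`` of the
    minimum) with a fixed size, e.g. 85 for age models or 54 for
    developmental-stage models.

    Parameters
    ----------
    n_estimators : trees in the full and sparse forests (default 500).
    cv_estimators : trees in the (cheaper) elimination forests.
    max_features : per-split feature fraction; 1/3 is the regression
        convention.
    n_select : fixed sparse size, or None for the CV rule.
    cv : folds for the elimination stage.
    tolerance : relative slack over the CV-error minimum.
    n_permutations : repeats for permutation importance.
    random_state : seed for every stochastic stage.
    """

    def __init__(self, n_estimators: int = 500, cv_estimators: int = 100,
                 max_features: float = 1 / 3, n_select=None, cv: int = 10,
                 tolerance: float = 0.05, n_permutations: int = 1,
                 random_state=None):
        self.n_estimators = n_estimators
        self.cv_estimators = cv_estimators
        self.max_features = max_features
        self.n_select = n_select
        self.cv = cv
        self.tolerance = tolerance
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _forest(self, n_estimators, seed):
        return RandomForestRegressor(
            n_estimators=n_estimators, max_features=self.max_features,
            oob_score=True, bootstrap=True, random_state=seed, n_jobs=1)

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.allclose(y, y[0]):
            raise ValueError("constant response")
        n, p = X.shape
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(p)]
        feature_names = np.asarray(feature_names, dtype=object)
        seed = (0 if self.random_state is None else int(self.random_state))

        self.full_forest_ = self._forest(self.n_estimators, seed).fit(X, y)
        self.oob_variance_explained_ = float(self.full_forest_.oob_score_)

        imp = permutation_importance_mse(
            self.full_forest_, X, y, n_repeats=self.n_permutations,
            seed=seed + 1)
        order = np.lexsort((feature_names, -imp))
        self.importances_ = imp
        self.ranking_ = pd.DataFrame({
            "feature": feature_names[order],
            "importance": imp[order],
            "rank": np.arange(1, p + 1)}).set_index("feature")
        self._rank_order = order

        sizes = halving_schedule(p)
        self.cv_curve_ = self._cv_eliminate(X, y, order, sizes, seed + 2)
        if self.n_select is not None:
            if self.n_select > p:
                raise ValueError("n_select exceeds feature count")
            chosen = int(self.n_select)
        else:
            chosen = select_subset_size(self.cv_curve_, self.tolerance)
        self.n_selected_ = chosen
        self.selected_idx_ = np.sort(order[:chosen])
        self.selected_features_ = list(feature_names[self.selected_idx_])

        self.forest_ = self._forest(self.n_estimators, seed + 3).fit(
            X[:, self.selected_idx_], y)
        self.feature_names_ = list(feature_names)
        self.n_features_in_ = p
        return self

    def _cv_eliminate(self, X, y, order, sizes, seed):
        n = len(y)
        if self.cv > n:
            raise ValueError(f"cv folds ({self.cv}) exceed n ({n})")
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=seed)
        errors = np.zeros((len(sizes), self.cv))
        for f, (tr, te) in enumerate(kf.split(X)):
            for s, size in enumerate(sizes):
                cols = order[:size]
                forest = RandomForestRegressor(
                    n_estimators=self.cv_estimators,
                    max_features=self.max_features,
                    random_state=seed + f, n_jobs=1)
                forest.fit(X[np.ix_(tr, cols)], y[tr])
                pred = forest.predict(X[np.ix_(te, cols)])
                errors[s, f] = np.mean((pred - y[te]) ** 2)
        return pd.DataFrame({"size": sizes, "cv_mse": errors.mean(axis=1)})

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        return self.forest_.predict(X[:, self.selected_idx_])


def halving_schedule(p: int) -> list[int]:
    """Subset sizes p, p/2, p/4, ..., 1 (integer halving, strictly
    decreasing)."""
    sizes = []
    s = p
    while s >= 1:
        sizes.append(int(s))
        if s == 1:
            break
        s = s // 2
    return sizes


def select_subset_size(cv_curve: pd.DataFrame, tolerance: float = 0.05) -> int:
    """Smallest subset size with CV MSE within ``tolerance`` of the
    minimum."""
    best = cv_curve["cv_mse"].min()
    ok = cv_curve[cv_curve["cv_mse"] <= (1.0 + tolerance) * best]
    return int(ok["size"].min())


# ---------------------------------------------------------------------------
# model container, fit / predict ops
# ---------------------------------------------------------------------------

@dataclass
class MaturityModel:
    """A fitted sparse forest plus its training provenance."""

    response: str               # "age_days" or "dev_stage"
    compartment: str
    selected_otus: list
    estimator: object           # anything with .predict(X) over selected OTUs
    training_samples: list = field(default_factory=list)
    training_sites: list = field(default_factory=list)
    training_seasons: list = field(default_factory=list)
    oob_variance_explained: float = float("nan")
    cv_curve: pd.DataFrame | None = None
    seed: int = 0


def _design_matrix(table: OtuTable, otu_ids, sample_ids) -> np.ndarray:
    return table.data.loc[list(otu_ids), list(sample_ids)].to_numpy().T


def fit_full_forest(table: OtuTable, metadata: pd.DataFrame, response: str,
                    split: SplitPlan, n_trees: int = 500, seed: int = 0,
                    n_permutations: int = 1):
    """Full forest over every OTU on the training half; importance
    ranking."""
    if table.unit != PER_MILLE:
        raise ValueError("expected a per-mille table")
    train = split.train_ids
    if len(train) < 20:
        raise ValueError("need >= 20 training samples")
    y = metadata.loc[train, response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("constant response on the training set")
    X = _design_matrix(table, table.otu_ids, train)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=1 / 3, oob_score=True,
        random_state=seed, n_jobs=1).fit(X, y)
    imp = permutation_importance_mse(forest, X, y, n_repeats=n_permutations,
                                     seed=seed + 1)
    names = np.asarray(table.otu_ids, dtype=object)
    order = np.lexsort((names, -imp))
    ranking = pd.DataFrame({
        "otu_id": names[order],
        "importance": imp[order],
        "rank": np.arange(1, len(names) + 1)}).set_index("otu_id")
    return forest, ranking


def cv_feature_elimination(table: OtuTable, metadata: pd.DataFrame,
                           response: str, ranking: pd.DataFrame,
                           train_ids, k: int = 10, seed: int = 0,
                           n_trees: int = 100) -> pd.DataFrame:
    """K-fold CV error over the halving schedule of top-ranked OTU
    subsets."""
    est = SparseRandomForestRegressor(cv_estimators=n_trees, cv=k,
                                      random_state=seed)
    X = _design_matrix(table, table.otu_ids, train_ids)
    y = metadata.loc[list(train_ids), response].to_numpy(dtype=float)
    ranked = list(ranking.index)
    order = np.asarray([table.otu_ids.index(o) for o in ranked])
    sizes = halving_schedule(len(ranked))
    return est._cv_eliminate(X, y, order, sizes, seed)


def fit_sparse_model(table: OtuTable, metadata: pd.DataFrame, response: str,
                     selected_otus, compartment: str = "pooled",
                     train_ids=None, n_trees: int = 500,
                     seed: int = 0) -> MaturityModel:
    """Refit a forest on only the selected OTUs."""
    selected = list(selected_otus)
    if not selected:
        raise ValueError("selected OTU set is empty")
    missing = set(selected) - set(table.otu_ids)
    if missing:
        raise ValueError(f"selected OTUs absent from table: "
                         f"{sorted(missing)[:5]}")
    ids = list(train_ids) if train_ids is not None else table.sample_ids
    X = _design_matrix(table, selected, ids)
    y = metadata.loc[ids, response].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=1 / 3, oob_score=True,
        random_state=seed, n_jobs=1).fit(X, y)
    md = metadata.loc[ids]
    return MaturityModel(
        response=response, compartment=compartment, selected_otus=selected,
        estimator=forest, training_samples=ids,
        training_sites=sorted(md["site"].unique().tolist()),
        training_seasons=sorted(md["season"].astype(str).unique().tolist()),
        oob_variance_explained=float(forest.oob_score_), seed=seed)


def predict_maturity(model: MaturityModel, table: OtuTable,
                     metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Predict microbiota age/stage for every sample in ``table``.

    Model OTUs missing from the table are imputed as 0 per mille with a
    logged warning; more than 50% missing aborts (the model does not
    transfer).
    """
    present = [o for o in model.selected_otus if o in set(table.otu_ids)]
    missing = [o for o in model.selected_otus if o not in set(table.otu_ids)]
    if len(missing) > 0.5 * len(model.selected_otus):
        raise ValueError(
            f"{len(missing)}/{len(model.selected_otus)} model OTUs missing "
            "from the table; model not transferable")
    if missing:
        logger.warning("imputing %d absent model OTUs as 0 per mille: %s",
                       len(missing), missing)
        warnings.warn(f"imputing {len(missing)} absent model OTUs as 0")
    mat = pd.DataFrame(0.0, index=model.selected_otus,
                       columns=table.sample_ids)
    mat.loc[present] = table.data.loc[present].to_numpy()
    pred = model.estimator.predict(mat.to_numpy().T)
    out = pd.DataFrame({"sample_id": table.sample_ids, "predicted": pred})
    if metadata is not None and model.response in metadata.columns:
        actual = metadata.loc[out["sample_id"], model.response].to_numpy(
            dtype=float)
        out["actual"] = actual
        out["residual"] = out["predicted"] - actual
    return out.set_index("sample_id", drop=False)


def fit_maturity_pipeline(table: OtuTable, metadata: pd.DataFrame,
                          response: str = "age_days",
                          compartment: str = "endosphere",
                          n_sparse=None, n_trees: int = 500,
                          cv_trees: int = 100, seed: int = 0):
    """End-to-end: split → full forest → CV elimination → sparse refit.

    Returns (model, split, ranking, cv_curve, test_predictions).
    """
    md = metadata[metadata["compartment"] == compartment]
    sub = table.select_samples(md["sample_id"])
    split = split_train_test(md, compartments=(compartment,), seed=seed)
    est = SparseRandomForestRegressor(
        n_estimators=n_trees, cv_estimators=cv_trees, n_select=n_sparse,
        random_state=seed)
    X = _design_matrix(sub, sub.otu_ids, split.train_ids)
    y = md.loc[split.train_ids, response].to_numpy(dtype=float)
    est.fit(X, y, feature_names=sub.otu_ids)
    model = MaturityModel(
        response=response, compartment=compartment,
        selected_otus=est.selected_features_, estimator=est.forest_,
        training_samples=split.train_ids,
        training_sites=sorted(md["site"].unique().tolist()),
        training_seasons=sorted(md["season"].astype(str).unique().tolist()),
        oob_variance_explained=est.oob_variance_explained_,
        cv_curve=est.cv_curve_, seed=seed)
    test_table = sub.select_samples(split.test_ids)
    preds = predict_maturity(model, test_table, md)
    return model, split, est.ranking_, est.cv_curve_, preds


# ---------------------------------------------------------------------------
# contrasts and marker aggregation
# ---------------------------------------------------------------------------

def maturity_contrast(predictions: pd.DataFrame, metadata: pd.DataFrame,
                      factors, tukey_factor: str | None = None,
                      response_col: str = "predicted"):
    """Sequential ANOVA of predicted values on design factors + Tukey HSD.

    ``response_col`` may be "residual" to contrast age-adjusted
    predictions (microbiota age relative to plant age).  Returns
    (anova_table, tukey_table); the Tukey contrasts compare the levels
    of ``tukey_factor`` (default: the last factor).
    """
    factors = list(factors)
    df = predictions.join(metadata.drop(
        columns=[c for c in predictions.columns if c in metadata.columns]))
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has < 2 levels")
    formula = f"{response_col} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    tf = tukey_factor or factors[-1]
    tuk = pairwise_tukeyhsd(df[response_col].to_numpy(),
                            df[tf].astype(str).to_numpy())
    tukey = pd.DataFrame(tuk.summary().data[1:],
                         columns=tuk.summary().data[0])
    return anova, tukey


def aggregate_marker_abundance(table: OtuTable,
                               calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample total per-mille abundance of each colonizer class.

    ``calls`` is a classify_colonizers table (otu_id, colonizer_class).
    Returns samples × {early, late, complex} sums.
    """
    if calls.empty:
        raise ValueError("no colonizer calls supplied")
    out = {}
    for cls in ("early", "late", "complex"):
        otus = [o for o in calls.loc[
            calls["colonizer_class"] == cls, "otu_id"]
            if o in set(table.otu_ids)]
        out[cls] = (table.data.loc[otus].sum(axis=0) if otus
                    else pd.Series(0.0, index=table.sample_ids))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# JSON serialization (portable, no pickle)
# ---------------------------------------------------------------------------

class JsonForest:
    """Predict-only forest reconstructed from exported tree arrays."""

    def __init__(self, trees: list[dict]):
        self.trees = trees

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(len(X))
        for t in self.trees:
            left = np.asarray(t["children_left"])
            right = np.asarray(t["children_right"])
            feat = np.asarray(t["feature"])
            thr = np.asarray(t["threshold"])
            val = np.asarray(t["value"])
            for i, x in enumerate(X):
                node = 0
                while left[node] != -1:
                    node = (left[node] if x[feat[node]] <= thr[node]
                            else right[node])
                acc[i] += val[node]
        return acc / len(self.trees)


def _forest_to_trees(forest: RandomForestRegressor) -> list[dict]:
    out = []
    for est in forest.estimators_:
        t = est.tree_
        out.append({
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "value": t.value.reshape(-1).tolist(),
        })
    return out


def save_model(model: MaturityModel, path) -> None:
    if isinstance(model.estimator, JsonForest):
        trees = model.estimator.trees
    else:
        trees = _forest_to_trees(model.estimator)
    doc = {
        "format": "rhizochron-maturity-model-v1",
        "response": model.response,
        "compartment": model.compartment,
        "selected_otus": list(model.selected_otus),
        "training_samples": list(model.training_samples),
        "training_sites": list(model.training_sites),
        "training_seasons": list(model.training_seasons),
        "oob_variance_explained": model.oob_variance_explained,
        "seed": model.seed,
        "trees": trees,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MaturityModel:
    with open(path) as fh:
        doc = json.load(fh)
    return MaturityModel(
        response=doc["response"], compartment=doc["compartment"],
        selected_otus=doc["selected_otus"],
        estimator=JsonForest(doc["trees"]),
        training_samples=doc["training_samples"],
        training_sites=doc["training_sites"],
        training_seasons=doc["training_seasons"],
        oob_variance_explained=doc["oob_variance_explained"],
        seed=doc["seed"])
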
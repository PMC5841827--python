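import numpy as np
import pandas as pd
import pytest

from rhizochron import (SimulationDesign, SparseRandomForestRegressor,
                        aggregate_marker_abundance, fit_maturity_pipeline,
                        fit_sparse_model, load_model, maturity_contrast,
                        normalize_per_mille, predict_maturity, save_model,
                        simulate_dataset, split_train_test)
from rhizochron.maturity import halving_schedule, select_subset_size
from conftest import make_metadata, per_mille_table


class TestSplit:
    def test_half_split_even_and_ceil_odd(self):
        md4 = make_metadata(4, ages=[7, 7, 7, 7])
        plan = split_train_test(md4, compartments=("endosphere",), seed=0)
        assert len(plan.train_ids) == 2 and len(plan.test_ids) == 2
        md3 = make_metadata(3, ages=[7, 7, 7])
        plan = split_train_test(md3, compartments=("endosphere",), seed=0)
        assert len(plan.train_ids) == 2 and len(plan.test_ids) == 1

    def test_disjoint_and_reproducible(self):
        md = make_metadata(24, ages=np.repeat([7, 14, 21], 8))
        p1 = split_train_test(md, compartments=("endosphere",), seed=3)
        p2 = split_train_test(md, compartments=("endosphere",), seed=3)
        assert set(p1.train_ids) & set(p1.test_ids) == set()
        assert p1.train_ids == p2.train_ids
        assert p1.test_ids == p2.test_ids

    def test_no_samples_errors(self):
        md = make_metadata(4, compartment="bulk_soil")
        with pytest.raises(ValueError):
            split_train_test(md, compartments=("endosphere",))


class TestSchedules:
    def test_halving_sizes_for_500(self):
        assert halving_schedule(500) == [500, 250, 125, 62, 31, 15, 7, 3, 1]

    def test_selection_rule_within_tolerance(self):
        curve = pd.DataFrame({"size": [100, 50, 25, 12, 6],
                              "cv_mse": [10.0, 10.2, 10.4, 10.6, 14.0]})
        assert select_subset_size(curve, tolerance=0.05) == 25
        assert select_subset_size(curve, tolerance=0.0) == 100


@pytest.fixture(scope="module")
def planted_regression():
    """One linear-in-age OTU among 200 noise OTUs."""
    rng = np.random.default_rng(0)
    n = 60
    ages = np.repeat(np.arange(10, 130, 20), 10).astype(float)
    X = rng.gamma(2.0, 5.0, (n, 201))
    X[:, 0] = ages + rng.normal(0, 3, n)
    names = [f"otu{i:03d}" for i in range(201)]
    return X, ages, names


class TestSparseForest:
    def test_planted_otu_ranks_top(self, planted_regression):
        X, y, names = planted_regression
        est = SparseRandomForestRegressor(
            n_estimators=200, cv_estimators=30, random_state=0)
        est.fit(X, y, feature_names=names)
        assert "otu000" in list(est.ranking_.index[:5])
        # better than the constant predictor on training data
        mse = np.mean((est.predict(X) - y) ** 2)
        assert mse < np.var(y)

    def test_shuffled_response_explains_nothing(self, planted_regression):
        X, y, names = planted_regression
        scores = []
        rng = np.random.default_rng(1)
        for k in range(10):
            est = SparseRandomForestRegressor(n_estimators=100,
                                              random_state=k)
            ys = rng.permutation(y)
            forest = est._forest(100, k).fit(X, ys)
            scores.append(forest.oob_score_)
        assert np.mean(np.asarray(scores) <= 0.1) >= 0.95

    def test_constant_response_errors(self, planted_regression):
        X, _, names = planted_regression
        est = SparseRandomForestRegressor(n_estimators=20)
        with pytest.raises(ValueError, match="constant"):
            est.fit(X, np.ones(len(X)))

    def test_fixed_override_selects_that_size(self, planted_regression):
        X, y, names = planted_regression
        est = SparseRandomForestRegressor(
            n_estimators=50, cv_estimators=20, n_select=85, random_state=0)
        est.fit(X, y, feature_names=names)
        assert est.n_selected_ == 85
        assert len(est.selected_features_) == 85

    def test_cv_folds_exceeding_n_errors(self):
        est = SparseRandomForestRegressor(cv=30, n_estimators=20,
                                          cv_estimators=10, random_state=0)
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="folds"):
            est.fit(rng.random((12, 5)), rng.random(12))


@pytest.fixture(scope="module")
def season():
    design = SimulationDesign(
        sites=("site_A",), compartments=("rhizosphere", "endosphere"),
        timepoints_days=tuple(range(7, 141, 14)), replicates_per_cell=4,
        seed=8)
    ds = simulate_dataset(design, n_otus=300,
                          site_specific_early_fraction=0.0,
                          static_site_fraction=0.0)
    return ds, normalize_per_mille(ds.table)


class TestModelLifecycle:
    def test_sparse_model_stores_list_and_refit_identical(self, season):
        ds, norm = season
        otus = list(ds.truth.index[:40])
        m1 = fit_sparse_model(norm, ds.metadata, "age_days", otus, seed=5)
        m2 = fit_sparse_model(norm, ds.metadata, "age_days", otus, seed=5)
        assert m1.selected_otus == otus
        p1 = predict_maturity(m1, norm)
        p2 = predict_maturity(m2, norm)
        assert np.allclose(p1["predicted"], p2["predicted"])

    def test_missing_selected_otu_errors(self, season):
        ds, norm = season
        with pytest.raises(ValueError, match="absent"):
            fit_sparse_model(norm, ds.metadata, "age_days", ["ghost"])

    def test_predict_imputes_few_missing_warns(self, season):
        ds, norm = season
        otus = list(ds.truth.index[:40])
        model = fit_sparse_model(norm, ds.metadata, "age_days", otus,
                                 seed=5)
        reduced = norm.select_otus(otus[1:])  # drop one model OTU
        with pytest.warns(UserWarning, match="imputing"):
            preds = predict_maturity(model, reduced, ds.metadata)
        assert len(preds) == norm.n_samples

    def test_predict_majority_missing_errors(self, season):
        ds, norm = season
        otus = list(ds.truth.index[:40])
        model = fit_sparse_model(norm, ds.metadata, "age_days", otus,
                                 seed=5)
        reduced = norm.select_otus(otus[30:])
        with pytest.raises(ValueError, match="not transferable"):
            predict_maturity(model, reduced, ds.metadata)

    def test_all_model_otus_zero_gives_constant_baseline(self, season):
        ds, norm = season
        otus = list(ds.truth.index[:30])
        model = fit_sparse_model(norm, ds.metadata, "age_days", otus,
                                 seed=5)
        zeroed = norm.copy()
        zeroed.data.loc[otus] = 0.0
        preds = predict_maturity(model, zeroed)
        assert preds["predicted"].nunique() == 1

    def test_json_round_trip_identical_predictions(self, season, tmp_path):
        ds, norm = season
        otus = list(ds.truth.index[:20])
        model = fit_sparse_model(norm, ds.metadata, "age_days", otus,
                                 n_trees=50, seed=5)
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        sub = norm.select_samples(norm.sample_ids[:25])
        a = predict_maturity(model, sub)["predicted"]
        b = predict_maturity(loaded, sub)["predicted"]
        assert np.allclose(a, b, atol=1e-9)
        assert loaded.selected_otus == otus


class TestEndToEnd:
    def test_training_r2_high_on_age_structured_data(self, season):
        ds, norm = season
        model, split, ranking, curve, preds = fit_maturity_pipeline(
            norm, ds.metadata, response="age_days",
            compartment="endosphere", n_sparse=50, n_trees=200,
            cv_trees=50, seed=1)
        md = ds.metadata
        train_tab = norm.select_samples(split.train_ids)
        train_preds = predict_maturity(model, train_tab, md)
        ss = np.sum((train_preds["predicted"] - train_preds["actual"]) ** 2)
        r2 = 1 - ss / np.sum(
            (train_preds["actual"] - train_preds["actual"].mean()) ** 2)
        assert r2 >= 0.9

    def test_sparse_not_much_worse_than_full_on_test(self, season):
        ds, norm = season
        model, split, ranking, curve, preds = fit_maturity_pipeline(
            norm, ds.metadata, response="age_days",
            compartment="endosphere", n_sparse=50, n_trees=200,
            cv_trees=50, seed=1)
        md = ds.metadata
        # full-model predictions on the same held-out samples
        full = fit_sparse_model(
            norm.select_samples(split.train_ids), md, "age_days",
            norm.otu_ids, n_trees=200, seed=1)
        test_tab = norm.select_samples(split.test_ids)
        sparse_preds = predict_maturity(model, test_tab, md)
        full_preds = predict_maturity(full, test_tab, md)

        def r2(p):
            ss = np.sum((p["predicted"] - p["actual"]) ** 2)
            return 1 - ss / np.sum((p["actual"] - p["actual"].mean()) ** 2)

        assert r2(sparse_preds) >= r2(full_preds) - 0.05

    def test_stage_model_beats_age_model_across_genotypes(self):
        # genotypes developing at rates differing by >= 30%
        design = SimulationDesign(
            sites=("site_A",), compartments=("endosphere",),
            timepoints_days=tuple(range(7, 141, 14)),
            replicates_per_cell=4, genotypes={"fast": 1.0, "slow": 0.65},
            seed=17)
        ds = simulate_dataset(design, n_otus=300, midpoint_day=60.0,
                              site_specific_early_fraction=0.0,
                              static_site_fraction=0.0)
        norm = normalize_per_mille(ds.table)
        md = ds.metadata
        _, split, _, _, stage_preds = fit_maturity_pipeline(
            norm, md, response="dev_stage", compartment="endosphere",
            n_sparse=54, n_trees=200, cv_trees=50, seed=2)
        _, _, _, _, age_preds = fit_maturity_pipeline(
            norm, md, response="age_days", compartment="endosphere",
            n_sparse=54, n_trees=200, cv_trees=50, seed=2)
        true_stage = md.loc[age_preds["sample_id"], "dev_stage"].to_numpy(
            dtype=float)
        # age predictions mapped to stage via the genotype-agnostic scale
        stage_from_age = np.clip(
            np.round(1 + 26 * age_preds["predicted"].to_numpy() / 140),
            1, 27)
        mse_stage = np.mean(
            (stage_preds["predicted"] - stage_preds["actual"]) ** 2)
        mse_age = np.mean((stage_from_age - true_stage) ** 2)
        assert mse_stage < mse_age


class TestContrastAndMarkers:
    def test_identical_groups_f_near_one(self):
        rng = np.random.default_rng(9)
        fs = []
        for k in range(30):
            md = make_metadata(40, ages=np.repeat([7, 14], 20))
            md["grp"] = ["a", "b"] * 20
            preds = pd.DataFrame({
                "sample_id": md["sample_id"],
                "predicted": rng.normal(50, 10, 40)}).set_index(
                    "sample_id", drop=False)
            anova, _ = maturity_contrast(preds, md, ["grp"])
            fs.append(anova.loc["C(grp)", "F"])
        assert abs(np.mean(fs) - 1.0) < 0.5

    def test_singular_factor_errors(self):
        md = make_metadata(10, ages=[7] * 10)
        preds = pd.DataFrame({"sample_id": md["sample_id"],
                              "predicted": np.arange(10.0)}).set_index(
                                  "sample_id", drop=False)
        with pytest.raises(ValueError, match="levels"):
            maturity_contrast(preds, md, ["treatment"])

    def test_marker_class_sums_bounded(self):
        calls = pd.DataFrame({
            "otu_id": ["a", "b", "c"],
            "colonizer_class": ["early", "late", "complex"]})
        t = per_mille_table([[200.0, 100.0], [300.0, 600.0],
                             [500.0, 300.0]], otu_ids=["a", "b", "c"])
        agg = aggregate_marker_abundance(t, calls)
        assert (agg.sum(axis=1) <= 1000 + 1e-9).all()
        assert agg.loc["s0", "early"] == 200.0
        assert agg.loc["s1", "late"] == 600.0
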
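import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from rhizochron import (OtuTable, between_site_distances, bray_curtis,
                        convergence_slopes, nb_exact_test,
                        normalize_per_mille, pcoa, site_specific_fraction,
                        site_specific_otus)
from rhizochron.site_dynamics import (equalize_library_sizes,
                                      estimate_dispersions,
                                      pco_trend_interaction)
from rhizochron import SimulationDesign, simulate_dataset, filter_prevalence
from rhizochron.structure import bray_curtis as bc
from conftest import make_metadata


def enumeration_oracle(counts_a, counts_b, dispersion):
    """Independent full-enumeration oracle for the conditional exact test.

    Enumerates every split (x, T−x) of the conditional distribution of
    the group-A sum given the total, computing unnormalized negative-
    binomial split weights directly from the Gamma-function form.
    """
    na, nb = len(counts_a), len(counts_b)
    sa = int(round(float(np.sum(counts_a))))
    sb = int(round(float(np.sum(counts_b))))
    t = sa + sb
    if t == 0:
        return 1.0
    weights = np.zeros(t + 1)
    for x in range(t + 1):
        if dispersion == 0:
            w = (gammaln(t + 1) - gammaln(x + 1) - gammaln(t - x + 1)
                 + x * np.log(na / (na + nb))
                 + (t - x) * np.log(nb / (na + nb)))
        else:
            ra, rb = na / dispersion, nb / dispersion
            w = (gammaln(x + ra) - gammaln(x + 1)
                 + gammaln(t - x + rb) - gammaln(t - x + 1))
        weights[x] = w
    weights = np.exp(weights - weights.max())
    probs = weights / weights.sum()
    return float(probs[probs <= probs[sa] * (1 + 1e-9)].sum())


class TestNbExactTest:
    def test_dispersion_zero_equals_binomial_tail(self):
        p, _ = nb_exact_test([9], [1], 0.0)
        w = stats.binom.pmf(np.arange(11), 10, 0.5)
        expected = w[w <= w[9] + 1e-12].sum()
        assert abs(p - expected) < 1e-12

    def test_symmetric_counts_p_one(self):
        p, lfc = nb_exact_test([5, 5], [5, 5], 0.3)
        assert p == 1.0
        assert abs(lfc) < 1e-12

    def test_zero_total_flagged(self):
        p, lfc = nb_exact_test([0, 0], [0, 0], 0.1)
        assert p == 1.0 and lfc == 0.0

    @pytest.mark.parametrize("dispersion", [0.0, 0.05, 0.2, 1.0])
    def test_matches_enumeration_oracle(self, dispersion):
        rng = np.random.default_rng(int(dispersion * 100))
        for _ in range(20):
            a = rng.integers(0, 80, rng.integers(2, 7))
            b = rng.integers(0, 80, rng.integers(2, 7))
            if a.sum() + b.sum() == 0:
                continue
            p, _ = nb_exact_test(a, b, dispersion)
            assert abs(p - enumeration_oracle(a, b, dispersion)) <= 1e-10

    def test_planted_fold_change_power(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 50
        for _ in range(n_sim):
            disp = 0.2
            r = 1 / disp
            a = rng.negative_binomial(r, r / (r + 50), 6)     # mean 50
            b = rng.negative_binomial(r, r / (r + 400), 6)    # 8-fold up
            p, lfc = nb_exact_test(a, b, disp)
            hits += (p <= 0.05 / 1000) and (lfc > 0)
        assert hits / n_sim >= 0.8

    def test_label_swap_flips_fold_change(self):
        p1, l1 = nb_exact_test([3, 4], [20, 25], 0.1)
        p2, l2 = nb_exact_test([20, 25], [3, 4], 0.1)
        assert p1 == p2
        assert abs(l1 + l2) < 0.2  # pseudo-count keeps it approximate


class TestDispersionAndDepth:
    def test_equalize_library_sizes_to_median(self):
        counts = pd.DataFrame({"a": [10, 10], "b": [40, 40],
                               "c": [20, 20]}, dtype=float)
        eq = equalize_library_sizes(counts)
        assert (eq.sum(axis=0) == 40.0).all()

    def test_moment_dispersions_recover_order(self):
        rng = np.random.default_rng(1)
        r_low, r_high = 1 / 0.05, 1 / 1.0
        a_low = rng.negative_binomial(r_low, r_low / (r_low + 100), (1, 40))
        a_high = rng.negative_binomial(r_high, r_high / (r_high + 100),
                                       (1, 40))
        mat = np.vstack([a_low, a_high]).astype(float)
        disp = estimate_dispersions(mat, mat, shrink=0.0)
        assert disp[1] > disp[0] >= 0


@pytest.fixture(scope="module")
def converging_dataset():
    design = SimulationDesign(timepoints_days=tuple(range(7, 141, 14)),
                              replicates_per_cell=3, seed=6)
    ds = simulate_dataset(design, n_otus=300)
    filtered, _ = filter_prevalence(ds.table)
    return ds, normalize_per_mille(filtered)


class TestConvergence:
    def test_rhizocompartments_converge_bulk_does_not(self,
                                                      converging_dataset):
        ds, norm = converging_dataset
        dist = bray_curtis(norm, transform="log2_pseudocount")
        pairs = between_site_distances(dist, ds.metadata)
        slopes = convergence_slopes(pairs)
        for comp in ("rhizosphere", "endosphere"):
            assert slopes.loc[comp, "slope"] < 0
            assert slopes.loc[comp, "p_value"] < 0.05
        assert slopes.loc["bulk_soil", "p_value"] > 0.05

    def test_distances_bounded_and_cross_site_only(self,
                                                   converging_dataset):
        ds, norm = converging_dataset
        dist = bray_curtis(norm)
        pairs = between_site_distances(dist, ds.metadata)
        assert pairs["distance"].between(0, 1).all()
        n_tp = ds.metadata["age_days"].nunique()
        # 3 reps per site -> 9 cross pairs per timepoint per compartment
        assert (pairs.groupby("compartment").size() == 9 * n_tp).all()


class TestSiteSpecificOtus:
    def test_planted_site_specific_recalled(self, converging_dataset):
        ds, _ = converging_dataset
        md = ds.metadata
        young = md[md["age_days"] <= 21]
        table = OtuTable(ds.table.data[young["sample_id"]])
        calls = site_specific_otus(table, md)
        sig = set(calls.loc[calls["significant_after_bonferroni"],
                            "otu_id"])
        norm_share = ds.table.data[young["sample_id"]].mean(axis=1)
        planted = [o for o in ds.truth.index[
            ds.truth["site_specific_to"] != "none"]
            if norm_share[o] >= 30]
        assert planted, "fixture should plant abundant site-specific OTUs"
        recall = np.mean([o in sig for o in planted])
        assert recall >= 0.9

    def test_null_family_wise_error_controlled(self):
        rng = np.random.default_rng(2)
        clean = 0
        n_runs = 40
        for run in range(n_runs):
            counts = rng.poisson(20, (60, 8)).astype(float)
            t = OtuTable(pd.DataFrame(
                counts, index=[f"o{i}" for i in range(60)],
                columns=[f"s{j}" for j in range(8)]))
            md = make_metadata(8, ages=[7.0] * 8)
            md["site"] = ["A"] * 4 + ["B"] * 4
            calls = site_specific_otus(t, md)
            clean += not calls["significant_after_bonferroni"].any()
        assert clean / n_runs >= 0.95

    def test_otu_zero_everywhere_not_called(self):
        t = OtuTable(pd.DataFrame({"s0": [5.0, 0.0], "s1": [7.0, 0.0],
                                   "s2": [6.0, 0.0], "s3": [5.0, 0.0]},
                                  index=["live", "dead"]))
        md = make_metadata(4, ages=[7.0] * 4)
        md["site"] = ["A", "A", "B", "B"]
        calls = site_specific_otus(t, md)
        assert "dead" not in set(calls["otu_id"])


class TestSiteSpecificFraction:
    def test_no_calls_gives_zero_fraction(self, converging_dataset):
        ds, norm = converging_dataset
        frac, trend = site_specific_fraction(norm, pd.DataFrame(),
                                             ds.metadata)
        assert (frac == 0).all()

    def test_declines_with_age_strongest_in_endosphere(
            self, converging_dataset):
        ds, norm = converging_dataset
        calls = site_specific_otus(
            OtuTable(ds.table.data.loc[norm.otu_ids]), ds.metadata)
        frac, trend = site_specific_fraction(norm, calls, ds.metadata)
        assert (frac <= 1000 + 1e-9).all()
        assert trend.loc["endosphere", "slope"] < 0
        assert trend.loc["endosphere", "p_value"] < 0.05
        assert (abs(trend.loc["endosphere", "slope"])
                > abs(trend.loc["rhizosphere", "slope"]))


class TestPcoTrendInteraction:
    @staticmethod
    def _run(seed, rates):
        design = SimulationDesign(
            sites=("site_A",), compartments=("endosphere",),
            timepoints_days=tuple(range(7, 141, 14)),
            replicates_per_cell=3, genotypes=rates, seed=seed)
        ds = simulate_dataset(
            design, n_otus=300, midpoint_day=38.0, midpoint_sd=3.0,
            curve_scale=4.0, site_specific_early_fraction=0.0,
            static_site_fraction=0.0,
            archetype_fractions={"early": 0.15, "late": 0.25,
                                 "complex": 0.0, "static": 0.60})
        filtered, _ = filter_prevalence(ds.table)
        norm = normalize_per_mille(filtered)
        ordn = pcoa(bc(norm, transform="log2_pseudocount"))
        return ds, pco_trend_interaction(ordn, ds.metadata, axis=1,
                                         split_day=84.0).set_index("window")

    def test_interaction_early_not_late_with_ordered_slopes(self):
        ds, res = self._run(3, {"fast": 1.0, "slow": 0.6})
        assert res.loc["early", "p_interaction"] < 0.05
        assert res.loc["late", "p_interaction"] > 0.05
        slopes = res.loc["early", "slopes"]
        assert abs(slopes["fast"]) > abs(slopes["slow"])

    def test_identical_genotypes_null(self):
        rng = np.random.default_rng(0)
        hits = 0
        for k in range(10):
            ds, res = self._run(100 + k, {"g1": 1.0, "g2": 1.0})
            hits += res.loc["early", "p_interaction"] < 0.05
        assert hits <= 1  # >= 90% non-significant under the null
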
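"""Between-site dynamics: convergence, skewed OTUs, genotype trajectories.

Cross-site community distances at shared time points quantify whether
two fields' root microbiota converge as plants age.  Site-skewed OTUs
are detected per time point with a conditional negative-binomial exact
test on equalized library sizes (the overdispersed analogue of the
two-sample Poisson exact test), and their aggregate per-mille share
yields the site-specific fraction trend.  Genotype trajectories along a
principal coordinate are compared with nested-model F-tests for an
age × genotype interaction before and after a split day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from skbio import DistanceMatrix
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_io import OtuTable
from .structure import OrdinationResult


# ---------------------------------------------------------------------------
# between-site convergence
# ---------------------------------------------------------------------------

def between_site_distances(dist: DistanceMatrix, metadata: pd.DataFrame,
                           ) -> pd.DataFrame:
    """Cross-site distances within each common time point × compartment.

    Returns one row per cross-site sample pair (compartment, age_days,
    distance).  Use :func:`convergence_slopes` for the per-compartment
    trend test.
    """
    md = metadata.loc[list(dist.ids)]
    sites = sorted(md["site"].unique())
    if len(sites) != 2:
        raise ValueError("exactly two sites required")
    idx = {s: i for i, s in enumerate(dist.ids)}
    rows = []
    for comp, sub in md.groupby("compartment", observed=True):
        common = [t for t in sorted(sub["age_days"].unique())
                  if set(sub.loc[sub["age_days"] == t, "site"]) == set(sites)]
        if len(common) < 3:
            continue
        for t in common:
            a = sub[(sub["age_days"] == t) & (sub["site"] == sites[0])]
            b = sub[(sub["age_days"] == t) & (sub["site"] == sites[1])]
            for sa in a["sample_id"]:
                for sb in b["sample_id"]:
                    rows.append({"compartment": comp, "age_days": float(t),
                                 "distance": dist.data[idx[sa], idx[sb]]})
    if not rows:
        raise ValueError("no common timepoints between the sites")
    return pd.DataFrame(rows)


def convergence_slopes(pair_distances: pd.DataFrame) -> pd.DataFrame:
    """OLS slope of cross-site distance on age, per compartment.

    Pair distances within one time point share that time point's
    sampling realization, so the t-test runs on per-time-point mean
    distances rather than treating every pair as independent.
    """
    rows = []
    for comp, sub in pair_distances.groupby("compartment", observed=True):
        means = sub.groupby("age_days")["distance"].mean()
        res = stats.linregress(means.index.to_numpy(), means.to_numpy())
        rows.append({"compartment": comp, "slope": res.slope,
                     "p_value": res.pvalue, "n_pairs": len(sub),
                     "n_timepoints": len(means)})
    return pd.DataFrame(rows).set_index("compartment")


# ---------------------------------------------------------------------------
# negative-binomial exact test
# ---------------------------------------------------------------------------

def nb_exact_test(counts_a, counts_b, dispersion: float = 0.0,
                  ) -> tuple[float, float]:
    """Conditional two-sided exact test of equal mean abundance.

    Group sums S_A, S_B are modeled as sums of i.i.d. negative-binomial
    counts with common mean and the given dispersion (variance
    μ + φμ²); conditioning on T = S_A + S_B makes the split distribution
    free of μ (negative hypergeometric; conditional binomial when
    φ = 0).  The two-sided p-value sums the probabilities of all splits
    no more probable than the observed one.  Returns (p_value,
    log2 fold change of group-B mean over group-A mean).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    na, nb = len(a), len(b)
    sa, sb = int(round(a.sum())), int(round(b.sum()))
    t = sa + sb
    lfc = float(np.log2((sb / nb + 0.5) / (sa / na + 0.5)))
    if t == 0:
        return 1.0, 0.0
    x = np.arange(t + 1)
    if dispersion == 0:
        logw = stats.binom.logpmf(x, t, na / (na + nb))
    else:
        ra, rb = na / dispersion, nb / dispersion
        logw = (gammaln(x + ra) - gammaln(x + 1)
                + gammaln(t - x + rb) - gammaln(t - x + 1))
        logw -= logsumexp(logw)
    log_obs = logw[sa]
    mask = logw <= log_obs + 1e-10  # tolerate fp ties
    p = float(np.exp(logsumexp(logw[mask]) - logsumexp(logw)))
    return min(p, 1.0), lfc


def estimate_dispersions(counts_a: np.ndarray, counts_b: np.ndarray,
                         shrink: float = 0.5) -> np.ndarray:
    """Method-of-moments tagwise dispersions, shrunk toward an
    abundance-trended common value.

    Per OTU, the NB dispersion φ solves var = μ + φμ² within each group;
    group estimates are averaged and clipped at 0.  The common value is
    a trend φ(μ) = a + b/μ fitted across OTUs — rare taxa are genuinely
    more dispersed in compositional count data, and a flat common value
    would let them through the exact test far too easily.  Tagwise
    estimates are then ``shrink``-weighted toward the trend.
    """
    def _tagwise(mat):
        mu = mat.mean(axis=1)
        v = mat.var(axis=1, ddof=1) if mat.shape[1] > 1 else np.zeros(
            mat.shape[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(mu > 0, (v - mu) / mu ** 2, 0.0)
        return phi

    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    tag = np.clip(0.5 * (_tagwise(a) + _tagwise(b)), 0.0, None)
    if len(tag) == 0:
        return tag
    mu = np.concatenate([a, b], axis=1).mean(axis=1)
    x = 1.0 / np.clip(mu, 0.5, None)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, tag, rcond=None)
    trend = np.clip(design @ coef, 0.0, None)
    # asymmetric moderation: below-trend tagwise values are mostly
    # estimation noise at few replicates and would make the exact test
    # anti-conservative, so they are raised to the trend; above-trend
    # values keep their tagwise component
    shrunk = (1.0 - shrink) * tag + shrink * trend
    return np.maximum(shrunk, trend)


def equalize_library_sizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Rescale every sample to the median depth and round to integers."""
    depths = counts.sum(axis=0)
    target = float(np.median(depths))
    return (counts.div(depths, axis=1) * target).round()


def site_specific_otus(table: OtuTable, metadata: pd.DataFrame,
                       alpha: float = 0.05,
                       dispersion_shrink: float = 0.5) -> pd.DataFrame:
    """Per time point × compartment exact tests for site-skewed OTUs.

    The Bonferroni family is the set of OTUs tested (nonzero total)
    within one time point × compartment.
    """
    md = metadata.loc[table.sample_ids]
    sites = sorted(md["site"].unique())
    if len(sites) != 2:
        raise ValueError("exactly two sites required")
    rows = []
    for (t, comp), sub in md.groupby(["age_days", "compartment"],
                                     observed=True):
        ids_a = sub.loc[sub["site"] == sites[0], "sample_id"]
        ids_b = sub.loc[sub["site"] == sites[1], "sample_id"]
        if ids_a.empty or ids_b.empty:
            continue
        counts = equalize_library_sizes(
            table.data[list(ids_a) + list(ids_b)])
        mat_a = counts[list(ids_a)].to_numpy()
        mat_b = counts[list(ids_b)].to_numpy()
        tested = np.flatnonzero(mat_a.sum(axis=1) + mat_b.sum(axis=1) > 0)
        m = len(tested)
        if m == 0:
            continue
        disp = estimate_dispersions(mat_a[tested], mat_b[tested],
                                    dispersion_shrink)
        for j, k in enumerate(tested):
            p, lfc = nb_exact_test(mat_a[k], mat_b[k], disp[j])
            sig = p <= alpha / m
            rows.append({
                "otu_id": table.otu_ids[k], "age_days": float(t),
                "compartment": comp, "log2_fold_change": lfc,
                "p_value": p, "significant_after_bonferroni": bool(sig),
                "skewed_to": (sites[1] if lfc > 0 else sites[0]) if sig
                else "none",
                "family_size": m,
            })
    return pd.DataFrame(rows)


def site_specific_fraction(table: OtuTable, calls: pd.DataFrame,
                           metadata: pd.DataFrame) -> tuple[pd.Series,
                                                            pd.DataFrame]:
    """Per-sample per-mille share of ever-site-specific OTUs + age trend.

    The site-specific set is the union over time points of significant
    calls.  Returns (per-sample fraction series, per-compartment OLS
    trend table).
    """
    if calls.empty or not calls["significant_after_bonferroni"].any():
        frac = pd.Series(0.0, index=table.sample_ids, name="fraction")
    else:
        otus = sorted(set(calls.loc[calls["significant_after_bonferroni"],
                                    "otu_id"]) & set(table.otu_ids))
        frac = table.data.loc[otus].sum(axis=0).rename("fraction")
    md = metadata.loc[table.sample_ids]
    rows = []
    for comp, sub in md.groupby("compartment", observed=True):
        y = frac.loc[sub["sample_id"]]
        if y.nunique() < 2:
            rows.append({"compartment": comp, "slope": 0.0, "p_value": 1.0})
            continue
        res = stats.linregress(sub["age_days"].to_numpy(dtype=float),
                               y.to_numpy())
        rows.append({"compartment": comp, "slope": res.slope,
                     "p_value": res.pvalue})
    return frac, pd.DataFrame(rows).set_index("compartment")


# ---------------------------------------------------------------------------
# principal-coordinate genotype trajectories
# ---------------------------------------------------------------------------

def pco_trend_interaction(ordination: OrdinationResult,
                          metadata: pd.DataFrame, axis: int = 2,
                          split_day: float = 84.0) -> pd.DataFrame:
    """Age × genotype interaction on a PCo axis, early vs late season.

    Within each compartment and each window (age ≤ split_day,
    age > split_day), compares ``coordinate ~ age`` against
    ``coordinate ~ age × genotype`` with a nested-model F-test and
    reports per-genotype slopes.
    """
    coord = ordination.coordinates[f"PCo{axis}"]
    md = metadata.loc[coord.index].copy()
    md["y"] = coord
    if md["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    rows = []
    for comp, sub_c in md.groupby("compartment", observed=True):
        for window, sub in (("early", sub_c[sub_c["age_days"] <= split_day]),
                            ("late", sub_c[sub_c["age_days"] > split_day])):
            sub = sub[sub.groupby("genotype", observed=True)["age_days"]
                      .transform("nunique") >= 3]
            if sub.empty or sub["genotype"].nunique() < 2:
                continue
            base = smf.ols("y ~ age_days", data=sub).fit()
            full = smf.ols("y ~ age_days * C(genotype)", data=sub).fit()
            cmp_tab = sm.stats.anova_lm(base, full)
            p_int = float(cmp_tab["Pr(>F)"].iloc[1])
            slopes = {}
            for geno, gg in sub.groupby("genotype", observed=True):
                slopes[str(geno)] = float(stats.linregress(
                    gg["age_days"], gg["y"]).slope)
            rows.append({"compartment": comp, "window": window,
                         "p_interaction": p_int, "slopes": slopes,
                         "n": len(sub)})
    return pd.DataFrame(rows)
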
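"""Taxon abundance trends: beta regression and colonizer classification.

Beta regression models a taxon's relative proportion y ∈ (0, 1) as
Beta(μφ, (1−μ)φ) with logit(μ) = β0 + β1·x and constant precision φ,
the natural likelihood for compositional proportions.  Spatial trends
use the compartment position code (bulk soil 0 → endosphere 3) as the
covariate; temporal trends use plant age in days within each
compartment.  Per-OTU colonizer classes (early / late / complex) come
from ordinary least-squares slopes of per-mille abundance on age with
Bonferroni-adjusted two-sided t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.othermod.betareg import BetaModel

from .core_io import OtuTable


def compress_boundaries(y: np.ndarray) -> np.ndarray:
    """Smithson–Verkuilen shrink: y' = (y·(n−1) + 0.5)/n, keeps y in (0,1)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if ((y <= 0) | (y >= 1)).any():
        y = (y * (n - 1) + 0.5) / n
    return y


class BetaRegression(BaseEstimator, RegressorMixin):
    """Beta regression with logit mean link and constant precision.

    Parameters
    ----------
    compress : bool, default True
        Apply the boundary compression y' = (y(n−1)+0.5)/n when any
        response sits on {0, 1}.

    Attributes
    ----------
    coef_ : ndarray, (2,) — intercept and slope on the logit scale.
    precision_ : float — ML estimate of φ.
    bse_ : ndarray — standard errors for (intercept, slope).
    zvalues_, pvalues_ : Wald z statistics and two-sided p-values.
    converged_ : bool
    """

    def __init__(self, compress: bool = True):
        self.compress = compress

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("single covariate expected")
        y = np.asarray(y, dtype=float)
        if len(y) < 10:
            raise ValueError("beta regression needs n >= 10")
        if self.compress:
            y = compress_boundaries(y)
        if ((y <= 0) | (y >= 1)).any():
            raise ValueError("responses must lie strictly in (0, 1)")
        exog = np.column_stack([np.ones_like(y), X[:, 0]])
        model = BetaModel(y, exog)  # constant φ via log-link intercept
        with np.errstate(all="ignore"):
            res = model.fit(disp=False, maxiter=200)
        self.coef_ = np.asarray(res.params[:2])
        self.precision_ = float(np.exp(res.params[2]))
        self.bse_ = np.asarray(res.bse[:2])
        self.zvalues_ = self.coef_ / self.bse_
        self.pvalues_ = 2 * stats.norm.sf(np.abs(self.zvalues_))
        self.converged_ = bool(res.mle_retvals.get("converged", True))
        self.loglik_ = float(res.llf)
        self.n_ = len(y)
        self._result = res
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.coef_[0] + self.coef_[1] * X[:, 0]
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class BetaRegFit:
    """Flat record of one beta-regression fit."""

    taxon: str
    covariate: str
    intercept: float
    slope: float
    precision: float
    se_intercept: float
    se_slope: float
    z_slope: float
    p_slope: float
    converged: bool
    n: int


def fit_beta_regression(y, x, taxon: str = "", covariate: str = "x",
                        ) -> BetaRegFit:
    """Fit one taxon's proportions against one covariate."""
    est = BetaRegression().fit(np.asarray(x, dtype=float), y)
    return BetaRegFit(
        taxon=taxon, covariate=covariate,
        intercept=float(est.coef_[0]), slope=float(est.coef_[1]),
        precision=est.precision_,
        se_intercept=float(est.bse_[0]), se_slope=float(est.bse_[1]),
        z_slope=float(est.zvalues_[1]), p_slope=float(est.pvalues_[1]),
        converged=est.converged_, n=est.n_)


def _trend_table(table: OtuTable, metadata: pd.DataFrame, x: np.ndarray,
                 covariate: str, alpha: float) -> pd.DataFrame:
    rows = []
    for taxon in table.otu_ids:
        y = table.data.loc[taxon].to_numpy() / 1000.0
        if (y == 0).all():
            continue  # absent everywhere: skipped
        try:
            fit = fit_beta_regression(y, x, taxon=taxon, covariate=covariate)
        except (ValueError, np.linalg.LinAlgError):
            continue
        rows.append(vars(fit))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    k = len(out)
    out["p_adjusted"] = np.minimum(out["p_slope"] * k, 1.0)
    out["significant"] = out["p_adjusted"] <= alpha
    return out.set_index("taxon")


def spatial_phylum_trends(phyla: OtuTable, metadata: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Beta-regression slope of each taxon's proportion on position 0–3."""
    md = metadata.loc[phyla.sample_ids]
    if md["position"].nunique() < 2:
        raise ValueError("samples must span >= 2 positions")
    return _trend_table(phyla, md, md["position"].to_numpy(dtype=float),
                        "position", alpha)


def temporal_phylum_trends(phyla: OtuTable, metadata: pd.DataFrame,
                           alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Per-compartment beta-regression slopes on plant age, keyed by
    compartment."""
    md = metadata.loc[phyla.sample_ids]
    out = {}
    for comp, sub in md.groupby("compartment", observed=True):
        tab = phyla.select_samples(sub["sample_id"])
        out[str(comp)] = _trend_table(
            tab, sub, sub["age_days"].to_numpy(dtype=float), "age_days",
            alpha)
    return out


# ---------------------------------------------------------------------------
# colonizer classification
# ---------------------------------------------------------------------------

@dataclass
class ColonizerCall:
    otu_id: str
    slope: float       # per-mille per day
    p_value: float
    p_adjusted: float
    colonizer_class: str  # early / late / complex


def classify_colonizers(table: OtuTable, metadata: pd.DataFrame,
                        otus=None, alpha: float = 0.05) -> pd.DataFrame:
    """OLS slope of per-mille abundance on age; early/late/complex calls.

    early: significantly negative slope; late: significantly positive;
    complex: slope not significantly different from 0 after Bonferroni
    over the supplied OTU set.
    """
    if otus is None:
        otus = table.otu_ids
    otus = list(otus)
    md = metadata.loc[table.sample_ids]
    age = md["age_days"].to_numpy(dtype=float)
    if len(np.unique(age)) < 3:
        raise ValueError("need >= 3 distinct ages")
    rows = []
    for otu in otus:
        y = table.data.loc[otu].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            rows.append((otu, 0.0, 1.0))
            continue
        res = stats.linregress(age, y)
        rows.append((otu, res.slope, res.pvalue))
    out = pd.DataFrame(rows, columns=["otu_id", "slope", "p_value"])
    m = len(out)
    out["p_adjusted"] = np.minimum(out["p_value"] * m, 1.0)
    sig = out["p_adjusted"] <= alpha
    out["colonizer_class"] = np.where(
        sig & (out["slope"] < 0), "early",
        np.where(sig & (out["slope"] > 0), "late", "complex"))
    return out.set_index("otu_id", drop=False)
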
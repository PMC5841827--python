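"""Community structure: dissimilarity, ordination, variance partitioning.

Bray-Curtis dissimilarities between per-mille profiles feed principal
coordinates analysis (classical metric scaling), adonis-style sequential
PERMANOVA, and a time-point similarity z-score matrix that summarizes
when in the season a compartment's community stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .core_io import OtuTable, PER_MILLE


def log2_transform(table: OtuTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(per-mille abundance + pseudocount), the ordination input scale."""
    return np.log2(table.data + pseudocount)


def bray_curtis(table: OtuTable, transform: str = "none",
                pseudocount: float = 1.0) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i).  ``transform="log2_pseudocount"``
    applies log2(abundance + pseudocount) first (the ordination
    convention); ``"none"`` uses per-mille abundances directly.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.data.sum(axis=0) <= 0).any():
        bad = table.data.columns[table.data.sum(axis=0) <= 0].tolist()
        raise ValueError(f"zero-total samples: {bad}")
    if transform == "log2_pseudocount":
        mat = log2_transform(table, pseudocount).to_numpy().T
    elif transform == "none":
        mat = table.data.to_numpy().T
    else:
        raise ValueError(f"unknown transform {transform!r}")
    dists = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(dists, ids=table.sample_ids)


def shannon(table: OtuTable) -> pd.Series:
    """Shannon diversity H = −Σ p ln p per sample (natural log)."""
    p = table.data.to_numpy()
    totals = p.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total sample")
    p = p / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=0), index=table.sample_ids,
                     name="shannon")


@dataclass
class OrdinationResult:
    """Principal coordinates, one row per sample."""

    coordinates: pd.DataFrame         # samples × axes ("PCo1", ...)
    eigenvalues: np.ndarray           # all eigenvalues, descending
    proportion_explained: np.ndarray  # per embedded (positive) axis


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical scaling: double-center −½d², eigendecompose.

    Coordinates span the positive-eigenvalue axes only; negative
    eigenvalues are reported in ``eigenvalues`` and the proportion-
    explained denominator is the sum of positive eigenvalues.
    """
    d = dist.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    denom = eigvals[pos].sum()
    prop = eigvals[pos] / denom if denom > 0 else np.zeros(pos.sum())
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA (adonis-style sequential partitioning)
# ---------------------------------------------------------------------------

def _model_matrix(metadata: pd.DataFrame, terms) -> list[np.ndarray]:
    """Dummy-coded design blocks, one per term, intercept implicit."""
    blocks = []
    for term in terms:
        col = metadata[term]
        if col.nunique() < 2:
            raise ValueError(f"term {term!r} has < 2 levels")
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
    return blocks


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(dist: DistanceMatrix, metadata: pd.DataFrame, terms,
              n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA of a distance matrix on design terms.

    Partitions SS_total = (1/n)·Σ_{i<j} d²_ij into per-term sums of
    squares in the given order, with pseudo-F and permutation p-values
    from unrestricted row permutations.  Returns a table with one row per
    term plus Residual and Total rows (columns: df, sum_of_squares, R2,
    pseudo_F, p_value).
    """
    terms = list(terms)
    missing = [t for t in terms if t not in metadata.columns]
    if missing:
        raise ValueError(f"terms missing from metadata: {missing}")
    md = metadata.loc[list(dist.ids)]
    d = dist.data
    n = d.shape[0]
    g = _gower_center(d)
    blocks = _model_matrix(md, terms)
    intercept = np.ones((n, 1))

    hats, dfs = [], []
    x = intercept
    h_prev = _hat(x)
    rank_prev = 1
    for b in blocks:
        x = np.hstack([x, b])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        hats.append((h_prev, h))
        dfs.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    h_full = h_prev
    df_resid = n - rank_prev

    # trace(H @ G) = sum(H * G) for symmetric G — permutations then cost
    # O(n^2) instead of a matrix product each
    diffs = [h - h0 for h0, h in hats]
    resid_proj = np.eye(n) - h_full

    def term_ss(gmat):
        ss = [np.sum(d * gmat) for d in diffs]
        ss_res = np.sum(resid_proj * gmat)
        return np.asarray(ss), ss_res

    ss_total = np.trace(g)  # = (1/n)·Σ_{i<j} d² for Gower-centered G
    ss_terms, ss_resid = term_ss(g)
    f_obs = (ss_terms / np.maximum(dfs, 1)) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_ss(gp)
        f_p = (ss_p / np.maximum(dfs, 1)) / (ss_res_p / df_resid)
        exceed += f_p >= f_obs
    pvals = (exceed + 1) / (n_perm + 1)

    rows = []
    for i, t in enumerate(terms):
        rows.append({"term": t, "df": dfs[i], "sum_of_squares": ss_terms[i],
                     "R2": ss_terms[i] / ss_total, "pseudo_F": f_obs[i],
                     "p_value": pvals[i]})
    rows.append({"term": "Residual", "df": df_resid,
                 "sum_of_squares": ss_resid, "R2": ss_resid / ss_total,
                 "pseudo_F": np.nan, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "sum_of_squares": ss_total,
                 "R2": 1.0, "pseudo_F": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# time-point similarity z-scores
# ---------------------------------------------------------------------------

def timepoint_similarity_z(dist: DistanceMatrix, metadata: pd.DataFrame,
                           compartment: str) -> pd.DataFrame:
    """Mean cross-time-point similarity (1 − d), z-scored per compartment.

    Cell (t1, t2) is the mean of (1 − d) over sample pairs spanning the
    two time points within ``compartment``; z-scoring uses the mean and
    sd across all cells of that compartment's matrix, so the grand mean
    of z-values is 0.
    """
    md = metadata.loc[list(dist.ids)]
    in_comp = md["compartment"] == compartment
    ids = np.asarray(dist.ids)[in_comp.to_numpy()]
    ages = md.loc[in_comp, "age_days"].to_numpy()
    tps = np.unique(ages)
    if len(tps) < 2:
        raise ValueError(f"need >= 2 timepoints in {compartment!r}")
    sub = dist.filter(ids).data
    sim = 1.0 - sub
    k = len(tps)
    mean_sim = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            ia = np.flatnonzero(ages == tps[a])
            ib = np.flatnonzero(ages == tps[b])
            if a == b:
                if len(ia) < 2:
                    continue
                vals = sim[np.ix_(ia, ia)][np.triu_indices(len(ia), 1)]
            else:
                vals = sim[np.ix_(ia, ib)].ravel()
            mean_sim[a, b] = vals.mean() if len(vals) else np.nan
    mu = np.nanmean(mean_sim)
    sd = np.nanstd(mean_sim)
    z = (mean_sim - mu) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(z, index=tps, columns=tps)
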
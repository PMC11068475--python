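"""From-scratch PERMANOVA with sequential SS, and nMDS ordination.

PERMANOVA partitions the Gower-centered inner-product matrix of a distance
matrix over the factorial terms G, M, E and their interactions in the
stated order (sequential / Type I sums of squares); pseudo-F p-values come
from joint row/column label permutations with the add-one convention.  nMDS
minimizes Kruskal stress-1 by iterative majorization with monotone
(isotonic) regression of the disparities, taking the best of many random
starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .ecology import DistanceMatrix
from .synthetic_data import TERMS

__all__ = ["PermanovaTable", "NmdsResult", "permanova",
           "permanova_by_stratum", "nmds", "design_matrix"]


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    n_starts: int
    best_start: int
    labels: list[str]


PermanovaTable = pd.DataFrame  # rows: terms + Residuals + Total


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

def _dummies(labels: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(labels))
    return (labels.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)


def design_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Cell-mean indicator columns for one factorial term (e.g. 'GxM')."""
    factors = term.split("x")
    cols = metadata[factors[0]].astype(str)
    for f in factors[1:]:
        cols = cols + "\x1f" + metadata[f].astype(str)
    return _dummies(cols)


def _hat(X: np.ndarray) -> np.ndarray:
    # projection onto the column space, tolerant of aliased columns
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > 1e-8 * s.max()
    U = U[:, keep]
    return U @ U.T


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame,
              terms=TERMS, n_perm: int = 999, seed: int = 0,
              batch: int = 256) -> PermanovaTable:
    """Sequential-SS PERMANOVA of a distance matrix over factorial terms.

    ``metadata`` must contain one row per matrix label, in order, with the
    factor columns referenced by ``terms``.  Returns a table with DF, SS,
    pseudo-F, R2 and permutation p-values, plus Residuals and Total rows.
    """
    if len(metadata) != dm.n:
        raise ValueError("metadata rows must match distance-matrix labels")
    if "sample" in metadata.columns and list(metadata["sample"]) != list(dm.labels):
        raise ValueError("metadata 'sample' column must match matrix labels")
    n = dm.n
    G = _gower_center(dm.values)
    ss_total = float(np.trace(G))

    dfs, hats = [], []
    X = np.ones((n, 1))
    prev_rank = 1
    H_prev = _hat(X)
    for term in terms:
        X = np.hstack([X, design_matrix(metadata, term)])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        dfs.append(rank - prev_rank)
        hats.append((H_prev, H))
        prev_rank, H_prev = rank, H
    H_full = H_prev
    df_resid = (n - 1) - sum(dfs)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for this design")

    # observed sequential SS: tr(H_k G) - tr(H_{k-1} G)
    ss = np.array([float(np.sum(H * G) - np.sum(Hp * G)) for Hp, H in hats])
    R = np.eye(n) - H_full
    ss_resid = float(np.sum(R * G))
    if ss_total <= 1e-12:
        return _degenerate_table(terms, dfs, df_resid, n)
    ms_resid = ss_resid / df_resid
    F = (ss / np.array(dfs)) / ms_resid

    # permutations: jointly permute rows/columns of G
    rng = np.random.default_rng(seed)
    diff = np.stack([H - Hp for Hp, H in hats])      # (t, n, n)
    exceed = np.zeros(len(terms))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        Gp = G[perms[:, :, None], perms[:, None, :]]          # (b, n, n)
        ss_p = np.einsum("tij,bij->bt", diff, Gp)
        ssr_p = np.einsum("ij,bij->b", R, Gp)
        F_p = (ss_p / np.array(dfs)) / (ssr_p / df_resid)[:, None]
        exceed += (F_p >= F[None, :] - 1e-12).sum(axis=0)
        done += b
    p = (exceed + 1) / (n_perm + 1)

    rows = []
    for i, term in enumerate(terms):
        rows.append({"term": term, "DF": dfs[i], "SS": ss[i], "F": F[i],
                     "R2": ss[i] / ss_total, "p": p[i]})
    rows.append({"term": "Residuals", "DF": df_resid, "SS": ss_resid,
                 "F": np.nan, "R2": ss_resid / ss_total, "p": np.nan})
    rows.append({"term": "Total", "DF": n - 1, "SS": ss_total, "F": np.nan,
                 "R2": 1.0, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def _degenerate_table(terms, dfs, df_resid, n):
    rows = [{"term": t, "DF": d, "SS": 0.0, "F": np.nan, "R2": np.nan,
             "p": np.nan} for t, d in zip(terms, dfs)]
    rows.append({"term": "Residuals", "DF": df_resid, "SS": 0.0, "F": np.nan,
                 "R2": np.nan, "p": np.nan})
    rows.append({"term": "Total", "DF": n - 1, "SS": 0.0, "F": np.nan,
                 "R2": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def permanova_by_stratum(dm: DistanceMatrix, metadata: pd.DataFrame,
                         focal_term: str = "G",
                         strata: tuple[str, ...] = ("M", "E"),
                         n_perm: int = 999, seed: int = 0):
    """Run a focal-term PERMANOVA within every stratum (e.g. each M x E).

    Returns {stratum levels -> PermanovaTable}; strata where the focal
    factor has fewer than 2 levels are skipped with a warning entry (None).
    """
    meta = metadata.reset_index(drop=True)
    results = {}
    groups = meta.groupby(list(strata), sort=True)
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        if sub.empty:
            continue
        if sub[focal_term].nunique() < 2 or len(sub) <= sub[focal_term].nunique():
            results[key] = None
            continue
        idx = sub.index.to_numpy()
        sub_dm = DistanceMatrix(values=dm.values[np.ix_(idx, idx)],
                                labels=[dm.labels[i] for i in idx])
        results[key] = permanova(sub_dm, sub.reset_index(drop=True),
                                 terms=(focal_term,), n_perm=n_perm, seed=seed)
    return results


# --------------------------------------------------------------------------
# nMDS
# --------------------------------------------------------------------------

def _stress1(d_emb: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_emb ** 2).sum()
    if denom <= 0:
        return np.inf
    return float(np.sqrt(((d_emb - disparities) ** 2).sum() / denom))


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 100, seed: int = 0,
         max_iter: int = 200, tol: float = 1e-6) -> NmdsResult:
    """Nonmetric MDS minimizing Kruskal stress-1, best of random starts.

    Each start runs iterative majorization (Guttman transform) alternating
    with isotonic regression of embedded distances on the observed
    dissimilarity order (primary tie treatment).
    """
    n = dm.n
    if n <= k:
        raise ValueError("need more samples than embedding dimensions")
    iu = np.triu_indices(n, k=1)
    diss = dm.values[iu]
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression()

    best = None
    for start in range(n_starts):
        X = rng.normal(size=(n, k))
        prev = np.inf
        for _ in range(max_iter):
            d = _pdist(X)[iu]
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            s = _stress1(d, dhat)
            if prev - s < tol:
                break
            prev = s
            X = _guttman(X, dhat, iu, n)
        if best is None or s < best[0]:
            best = (s, X, start)
    stress, X, start = best
    X = X - X.mean(axis=0)
    return NmdsResult(coordinates=X, stress=stress, n_starts=n_starts,
                      best_start=start, labels=list(dm.labels))


def _pdist(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def _guttman(X, dhat, iu, n):
    d = _pdist(X)[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 1e-12, dhat / d, 0.0)
    B = np.zeros((n, n))
    B[iu] = -ratio
    B = B + B.T
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n
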
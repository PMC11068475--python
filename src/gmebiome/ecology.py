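"""Diversity machinery: analytic rarefaction, coverage standardization,
Shannon index, Morisita-Horn dissimilarity, Mantel test and IBS kinship.

Coverage standardization follows the endpoint-slope idea of coverage-based
rarefaction: the expected richness gain from one more read at full depth is
f1/N (the singleton fraction); the sample with the largest endpoint slope
has the lowest coverage, and every other sample is subsampled to the
largest depth whose slope still reaches that reference slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DistanceMatrix", "expected_richness", "endpoint_slope",
    "coverage_standardize", "shannon", "morisita_horn",
    "morisita_horn_matrix", "mantel", "ibs_kinship",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity with sample labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# --------------------------------------------------------------------------
# rarefaction
# --------------------------------------------------------------------------

def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def expected_richness(counts, m: int) -> float:
    """Expected number of taxa observed in a subsample of size m.

    E[S_m] = S - sum_i C(N - N_i, m) / C(N, m), evaluated in log space.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    if N < 1:
        raise ValueError("total count must be at least 1")
    if m < 0 or m > N:
        raise ValueError("subsample size m must satisfy 0 <= m <= N")
    if m == 0:
        return 0.0
    S = len(counts)
    keep = N - counts >= m
    if not keep.any():
        return float(S)
    lp = _log_choose(N - counts[keep], m) - _log_choose(N, m)
    return float(S - np.exp(lp).sum())


def endpoint_slope(counts, m: int | None = None) -> float:
    """Slope of the rarefaction curve at depth m: E[S_m] - E[S_{m-1}].

    At full depth (m = N) this equals f1/N, the singleton fraction.
    """
    counts = np.asarray(counts, dtype=float)
    N = int(counts.sum())
    if m is None:
        m = N
    if m < 1:
        raise ValueError("m must be at least 1")
    return expected_richness(counts, m) - expected_richness(counts, m - 1)


def _subsample_without_replacement(rng, counts: np.ndarray, m: int) -> np.ndarray:
    return rng.multivariate_hypergeometric(counts.astype(np.int64), int(m))


def coverage_standardize(count_matrix: pd.DataFrame, seed: int = 0):
    """Rarefy all samples to match the coverage of the worst sample.

    The reference slope s* is the maximum endpoint slope across samples
    (the lowest-coverage sample); each sample is subsampled without
    replacement to the largest depth m with slope(m) >= s*.  Returns
    (rarefied DataFrame, report DataFrame with per-sample slope and depth).
    """
    if count_matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    counts = count_matrix.to_numpy()
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("every sample needs a positive total")
    rng = np.random.default_rng(seed)
    slopes = np.array([endpoint_slope(row) for row in counts])
    s_star = slopes.max()
    ref_idx = int(slopes.argmax())

    depths = np.empty(len(counts), dtype=int)
    out = np.zeros_like(counts)
    warned = []
    for i, row in enumerate(counts):
        N = int(row.sum())
        if (row > 0).sum() < 2:
            depths[i] = N
            out[i] = row
            warned.append(count_matrix.index[i])
            continue
        if i == ref_idx or endpoint_slope(row) >= s_star:
            depths[i] = N
            out[i] = row
            continue
        # slope(m) is non-increasing in m; binary search for the largest m
        # with slope(m) >= s*.  slope(1) = 1 >= s* always.
        lo, hi = 1, N  # slope(lo) >= s*, slope(hi) < s*
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if endpoint_slope(row, mid) >= s_star:
                lo = mid
            else:
                hi = mid
        depths[i] = lo
        out[i] = _subsample_without_replacement(rng, row, lo)
    rarefied = pd.DataFrame(out, index=count_matrix.index,
                            columns=count_matrix.columns, dtype=int)
    report = pd.DataFrame({"endpoint_slope": slopes, "target_depth": depths,
                           "original_depth": counts.sum(axis=1).astype(int)},
                          index=count_matrix.index)
    report.attrs["reference_slope"] = float(s_star)
    report.attrs["degenerate_samples"] = warned
    return rarefied, report


# --------------------------------------------------------------------------
# diversity indices
# --------------------------------------------------------------------------

def shannon(frequencies, base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p (natural log by default)."""
    p = np.asarray(frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must sum to 1")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity 1 - C_H in [0, 1].

    C_H = 2 sum x_i y_i / ((sum x_i^2/X^2 + sum y_i^2/Y^2) * X * Y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("both vectors need positive totals")
    d = ((x ** 2).sum() / X ** 2 + (y ** 2).sum() / Y ** 2) * X * Y
    sim = 2.0 * (x * y).sum() / d
    return float(1.0 - sim)


def morisita_horn_matrix(count_matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Morisita-Horn dissimilarity over the rows of a table."""
    M = count_matrix.to_numpy(float)
    totals = M.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total")
    P = M / totals[:, None]
    simpson = (P ** 2).sum(axis=1)
    cross = P @ P.T
    sim = 2.0 * cross / (simpson[:, None] + simpson[None, :])
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    D = (D + D.T) / 2
    return DistanceMatrix(values=D, labels=list(count_matrix.index))


# --------------------------------------------------------------------------
# Mantel test and kinship
# --------------------------------------------------------------------------

def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
           seed: int = 0):
    """One-sided Mantel test for positive association of two matrices.

    r is the Pearson correlation of the upper triangles; the p-value is
    (#{permuted r >= observed} + 1) / (n_perm + 1) under joint row/column
    permutation of d2.
    """
    if d1.labels != d2.labels:
        raise ValueError("matrices must share labels in the same order")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    r_obs = _pearson(v1, d2.values[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        count += _pearson(v1, d2.values[np.ix_(p, p)][iu]) >= r_obs
    return float(r_obs), (count + 1) / (n_perm + 1)


def _pearson(a, b) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        raise ValueError("zero-variance distances in Mantel test")
    return float((a * b).sum() / denom)


def ibs_kinship(genotype_matrix: pd.DataFrame) -> pd.DataFrame:
    """Identity-by-state similarity from 0/1/2 genotype calls.

    IBS(a, b) = mean over loci where both calls are present of
    (2 - |g_a - g_b|) / 2.  Missing calls are NaN.
    """
    G = genotype_matrix.to_numpy(float)
    n = G.shape[0]
    K = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(G[i]) | np.isnan(G[j]))
            if not ok.any():
                raise ValueError(
                    f"no shared non-missing loci between rows {i} and {j}")
            K[i, j] = K[j, i] = np.mean((2.0 - np.abs(G[i, ok] - G[j, ok])) / 2.0)
    ids = list(genotype_matrix.index)
    return pd.DataFrame(K, index=ids, columns=ids)
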
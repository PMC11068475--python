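"""Microbiome-kinship variance decomposition of genotype-standardized
shoot length.

The model is y = X beta + u + e with u ~ (0, sigma2_g K) and
e ~ (0, sigma2_e I), where K is the Morisita-Horn community similarity
(1 - dissimilarity) across individuals, eigen-clipped to positive
semidefinite.  The restricted likelihood is profiled over
delta = sigma2_e / sigma2_g via a single eigendecomposition (the EMMA
device), maximized on a log-spaced delta grid refined by local search.
The reported fraction sigma2_g / (sigma2_g + sigma2_e) is the share of
phenotypic variance tracked by microbiome similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .ecology import morisita_horn_matrix

__all__ = ["KinshipMatrix", "VarCompResult", "standardize_by_genotype",
           "microbiome_kinship", "reml_variance"]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    labels: list[str]
    psd_adjustment: float = 0.0      # |most negative eigenvalue| clipped

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")


@dataclass
class VarCompResult:
    sigma2_g: float
    sigma2_e: float
    log_reml: float
    delta_grid_trace: pd.DataFrame = field(repr=False, default=None)
    boundary: bool = False

    @property
    def fraction(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0


def standardize_by_genotype(phenotypes, genotype_labels) -> np.ndarray:
    """Subtract the per-genotype mean; output means are exactly 0 per G."""
    y = np.asarray(phenotypes, float)
    labels = np.asarray(genotype_labels)
    if len(y) != len(labels):
        raise ValueError("phenotype and label lengths differ")
    out = np.empty_like(y)
    for g in np.unique(labels):
        mask = labels == g
        if mask.sum() == 1:
            warnings.warn(f"genotype {g!r} has a single individual; centered to 0")
        out[mask] = y[mask] - y[mask].mean()
    return out


def microbiome_kinship(frequency_matrix: pd.DataFrame) -> KinshipMatrix:
    """Community similarity kinship K = 1 - Morisita-Horn dissimilarity.

    The diagonal is 1; eigenvalues below zero are clipped to zero and the
    magnitude of the largest clip is recorded.
    """
    if frequency_matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dm = morisita_horn_matrix(frequency_matrix)
    K = 1.0 - dm.values
    np.fill_diagonal(K, 1.0)
    w, V = np.linalg.eigh(K)
    adj = float(max(0.0, -w.min()))
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        K = (V * w) @ V.T
        K = (K + K.T) / 2
    return KinshipMatrix(values=K, labels=list(frequency_matrix.index),
                         psd_adjustment=adj)


def _reml_loglik(delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    nq = len(lam)
    denom = lam + delta
    s = float((eta2 / denom).sum())
    return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1 - np.log(s))
                  - np.log(denom).sum())


def reml_variance(y, K: KinshipMatrix | np.ndarray,
                  grid_points: int = 100,
                  delta_range: tuple[float, float] = (1e-5, 1e5)) -> VarCompResult:
    """EMMA-style REML estimate of (sigma2_g, sigma2_e) for y = mu + u + e.

    X is an intercept; the restricted likelihood is profiled over
    delta = sigma2_e/sigma2_g using the eigendecomposition of the projected
    kinship, maximized on a log-spaced grid with local refinement between
    bracketing grid points.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    y = np.asarray(y, float)
    n = len(y)
    if Kv.shape != (n, n):
        raise ValueError("y length must match kinship dimension")
    w = np.linalg.eigvalsh(Kv)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("kinship is not PSD; apply eigenvalue clipping first")
    if np.allclose(y, y[0]):
        return VarCompResult(0.0, 0.0, log_reml=np.nan, boundary=True)

    # restricted eigen-space: project out the intercept
    X = np.ones((n, 1))
    S = np.eye(n) - X @ X.T / n
    SKS = S @ Kv @ S
    lam_all, U = np.linalg.eigh((SKS + SKS.T) / 2)
    # keep the n-1 eigenpairs spanning the contrast space (drop the
    # eigenvalue paired with the intercept direction, numerically ~0 and
    # flagged by its eigenvector being ~constant)
    const_dir = np.abs(U.T @ np.ones(n) / np.sqrt(n))
    drop = int(np.argmax(const_dir))
    keep = np.ones(n, bool)
    keep[drop] = False
    lam = np.clip(lam_all[keep], 0.0, None)
    eta = (U[:, keep]).T @ (y - y.mean())   # centered: intercept projected out
    eta2 = eta ** 2

    grid = np.geomspace(delta_range[0], delta_range[1], grid_points)
    ll = np.array([_reml_loglik(d, lam, eta2) for d in grid])
    i = int(np.argmax(ll))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(lambda t: -_reml_loglik(np.exp(t), lam, eta2),
                          bounds=(np.log(lo), np.log(hi)), method="bounded")
    delta = float(np.exp(res.x))
    best_ll = _reml_loglik(delta, lam, eta2)
    if best_ll < ll[i]:
        delta, best_ll = float(grid[i]), float(ll[i])
    boundary = i in (0, len(grid) - 1)
    if boundary:
        warnings.warn("REML optimum at the delta grid boundary; variance "
                      "components weakly identified")

    nq = len(lam)
    sigma2_g = float((eta2 / (lam + delta)).sum() / nq)
    sigma2_e = float(delta * sigma2_g)
    trace = pd.DataFrame({"delta": grid, "log_reml": ll})
    result = VarCompResult(sigma2_g=sigma2_g, sigma2_e=sigma2_e,
                           log_reml=float(best_ll), delta_grid_trace=trace,
                           boundary=boundary)
    assert best_ll >= ll.max() - 1e-9
    return result
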
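"""Pot-permutation resampling: plants in one pot share a microenvironment,
so effects are re-estimated over many random selections of one pot per
G x M x E combination.  The headline summary is the fraction of iterations
in which the genotype-by-inoculant effect size exceeds the inoculant main
effect (eta^2(GxM) > eta^2(M))."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecology import morisita_horn_matrix
from .ordination_stats import permanova
from .pheno_glm import anova_type2, fit_gamma_glm
from .synthetic_data import TERMS

__all__ = ["PermutationSummary", "select_one_pot", "pot_permutation_glm",
           "pot_permutation_permanova"]


@dataclass
class PermutationSummary:
    """Per-term effect-size distributions over resampling iterations."""

    samples: pd.DataFrame            # iterations x terms
    n_iter: int
    n_failed: int = 0
    metric: str = "eta2"

    @property
    def mean(self) -> pd.Series:
        return self.samples.mean()

    def quantiles(self, q=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        return self.samples.quantile(list(q))

    @property
    def fraction_gxm_gt_m(self) -> float:
        # ties count as "not greater"
        return float((self.samples["GxM"] > self.samples["M"]).mean())


def select_one_pot(metadata: pd.DataFrame, seed: int = 0,
                   combo=("G", "M", "E"), pot_col: str = "pot") -> pd.DataFrame:
    """Keep all individuals of one uniformly chosen pot per combination."""
    rng = np.random.default_rng(seed)
    keep = []
    for _, sub in metadata.groupby(list(combo), sort=True):
        pots = sorted(sub[pot_col].unique())
        if not pots:
            raise ValueError("combination without pots")
        chosen = pots[rng.integers(0, len(pots))]
        keep.append(sub[sub[pot_col] == chosen])
    out = pd.concat(keep)
    assert out.groupby(list(combo))[pot_col].nunique().eq(1).all()
    return out.sort_index()


def pot_permutation_glm(table: pd.DataFrame, response: str = "SL",
                        terms=TERMS, n_iter: int = 1000,
                        seed: int = 0) -> PermutationSummary:
    """n_iter rounds of one-pot selection -> gamma GLM -> type II eta^2.

    Iterations whose GLM fails are skipped and counted; more than 10%
    failures raises.
    """
    rng = np.random.default_rng(seed)
    rows, failed = [], 0
    while len(rows) < n_iter:
        sub = select_one_pot(table, seed=int(rng.integers(2 ** 31)))
        try:
            fit = fit_gamma_glm(sub, response, terms)
            tab = anova_type2(fit)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
            if failed > max(1, 0.1 * n_iter):
                raise RuntimeError("more than 10% of GLM iterations failed")
            continue
        rows.append(tab.loc[list(terms), "eta2"])
    samples = pd.DataFrame(rows, index=range(n_iter))[list(terms)]
    return PermutationSummary(samples=samples, n_iter=n_iter, n_failed=failed)


def pot_permutation_permanova(count_matrix: pd.DataFrame,
                              metadata: pd.DataFrame, terms=TERMS,
                              n_iter: int = 1000, n_perm_inner: int = 999,
                              seed: int = 0) -> PermutationSummary:
    """As pot_permutation_glm but for community R2 via PERMANOVA.

    Per iteration: select one pot per combination, recompute Morisita-Horn
    distances on the retained samples, run the factorial PERMANOVA, and
    collect each term's R2.
    """
    meta = metadata.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rows, failed = [], 0
    while len(rows) < n_iter:
        sub = select_one_pot(meta, seed=int(rng.integers(2 ** 31)))
        idx = sub.index.to_numpy()
        try:
            dm = morisita_horn_matrix(count_matrix.iloc[idx])
            tab = permanova(dm, sub.reset_index(drop=True), terms=terms,
                            n_perm=n_perm_inner,
                            seed=int(rng.integers(2 ** 31)))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
            if failed > max(1, 0.1 * n_iter):
                raise RuntimeError("more than 10% of PERMANOVA iterations failed")
            continue
        rows.append(tab.loc[list(terms), "R2"])
    samples = pd.DataFrame(rows, index=range(n_iter))[list(terms)]
    return PermutationSummary(samples=samples, n_iter=n_iter,
                              n_failed=failed, metric="R2")
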
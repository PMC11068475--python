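"""Gamma GLMs for phenotypes and alpha diversity: type II deviance ANOVA
with F-tests and eta-squared, Tukey-Kramer contrasts, Pearson phenotype
correlations, Shapiro-Wilk screening, and the pot intraclass correlation.

Phenotypes are strictly positive and right-skewed, so the models use a
gamma error distribution with a log link.  Effect sizes are reported as
eta^2 = SS(term) / (sum of term SS + residual SS), with sums of squares on
the deviance scale: SS(term) is the deviance drop when the term enters the
type II comparison, and the residual SS is the full model's deviance, so
F = (SS/DF)/(SS_resid/DF_resid) reproduces the usual F summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .synthetic_data import TERMS

__all__ = [
    "GlmFit", "AnovaTable", "fit_gamma_glm", "anova_type2", "tukey_kramer",
    "phenotype_correlations", "shapiro_screen", "icc_pot", "icc_all",
]

AnovaTable = pd.DataFrame


@dataclass
class GlmFit:
    """A fitted gamma/log-link GLM plus the design bookkeeping."""

    result: object                  # statsmodels GLMResults
    table: pd.DataFrame
    response: str
    terms: tuple[str, ...]
    design_info: dict = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    @property
    def fitted_means(self) -> np.ndarray:
        return np.asarray(self.result.fittedvalues)

    @property
    def dispersion(self) -> float:
        return float(self.result.pearson_chi2 / self.result.df_resid)


def _factor_dummies(table: pd.DataFrame, factor: str):
    """Treatment coding: indicator columns for all levels but the first."""
    lab = table[factor].astype(str)
    levels = sorted(pd.unique(lab))
    block = (lab.to_numpy()[:, None] == np.array(levels[1:])[None, :]).astype(float)
    return block, [f"{factor}[{lv}]" for lv in levels[1:]]


def _build_design(table: pd.DataFrame, terms) -> tuple[np.ndarray, list, dict]:
    """Factorial design with intercept; interactions are products of the
    treatment-coded main-effect columns, so the design is full rank for any
    complete factorial."""
    n = len(table)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    slices = {}
    pos = 1
    for term in terms:
        factors = term.split("x")
        block, bnames = _factor_dummies(table, factors[0])
        for f in factors[1:]:
            b2, n2 = _factor_dummies(table, f)
            block = np.einsum("ij,ik->ijk", block, b2).reshape(n, -1)
            bnames = [f"{a}:{b}" for a in bnames for b in n2]
        blocks.append(block)
        names += bnames
        slices[term] = slice(pos, pos + block.shape[1])
        pos += block.shape[1]
    return np.hstack(blocks), names, slices


def fit_gamma_glm(table: pd.DataFrame, response: str,
                  terms=TERMS) -> GlmFit:
    """Fit a gamma GLM with log link of ``response`` on factorial terms.

    Fitting is IRLS to convergence; the dispersion estimate is the Pearson
    statistic over the residual degrees of freedom.
    """
    y = table[response].to_numpy(float)
    if (y <= 0).any():
        raise ValueError("gamma GLM requires a strictly positive response")
    X, names, slices = _build_design(table, terms)
    if np.ptp(y) == 0:
        # perfect fit: intercept-only with zero deviance (statsmodels'
        # gamma deviance is indeterminate at an exact fit)
        result = _ConstantFit(y, X)
        return GlmFit(result=result, table=table, response=response,
                      terms=tuple(terms),
                      design_info={"X": X, "names": names, "slices": slices})
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    result = model.fit(maxiter=200, tol=1e-9)
    if not result.converged:
        raise RuntimeError(
            f"gamma GLM did not converge in {result.fit_history['iteration']} iterations")
    return GlmFit(result=result, table=table, response=response,
                  terms=tuple(terms),
                  design_info={"X": X, "names": names, "slices": slices})


class _ConstantFit:
    """Degenerate GLM result for a constant response (zero deviance)."""

    def __init__(self, y, X):
        self.params = np.zeros(X.shape[1])
        self.params[0] = np.log(y[0])
        self.bse = np.zeros(X.shape[1])
        self.deviance = 0.0
        self.fittedvalues = np.full(len(y), y[0])
        self.df_resid = len(y) - np.linalg.matrix_rank(X)
        self.pearson_chi2 = 0.0
        self.converged = True

    def cov_params(self):
        p = len(self.params)
        return np.zeros((p, p))


def _contains(term_a: str, term_b: str) -> bool:
    """True if term_a contains term_b as a marginal sub-term."""
    return set(term_b.split("x")) <= set(term_a.split("x"))


def _deviance_of(table, response, terms):
    if not terms:
        terms = ()
    y = table[response].to_numpy(float)
    X, _, _ = _build_design(table, terms)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=200, tol=1e-9)
    return float(res.deviance), res

def anova_type2(fit: GlmFit) -> AnovaTable:
    """Type II deviance ANOVA with F-tests and eta^2 effect sizes.

    Each term T is tested by comparing the model of all terms that do not
    contain T (marginality respected) against that model plus T.  SS values
    are deviance differences; the residual SS is the full model's deviance.
    """
    table, response, terms = fit.table, fit.response, list(fit.terms)
    full_dev = fit.deviance
    df_resid = int(fit.result.df_resid)

    dev_cache: dict[tuple, float] = {tuple(sorted(terms)): full_dev}

    def dev(term_set):
        key = tuple(sorted(term_set))
        if key not in dev_cache:
            dev_cache[key], _ = _deviance_of(table, response,
                                             [t for t in terms if t in term_set])
        return dev_cache[key]

    rows = []
    for term in terms:
        base = {t for t in terms if t != term and not _contains(t, term)}
        d0 = dev(base)
        d1 = dev(base | {term})
        ss = d0 - d1
        df = _term_df(table, terms, term)
        if df == 0:
            raise ValueError(f"term {term} is aliased (0 df)")
        F = (ss / df) / (full_dev / df_resid)
        p = stats.f.sf(F, df, df_resid)
        rows.append({"term": term, "DF": df, "SS": ss, "F": F, "p": p})
    ss_terms = sum(r["SS"] for r in rows)
    for r in rows:
        r["eta2"] = r["SS"] / (ss_terms + full_dev)
    rows.append({"term": "Residuals", "DF": df_resid, "SS": full_dev,
                 "F": np.nan, "p": np.nan,
                 "eta2": full_dev / (ss_terms + full_dev)})
    return pd.DataFrame(rows).set_index("term")[["DF", "SS", "F", "eta2", "p"]]


def _term_df(table, terms, term):
    """DF of a term as the rank increase when it joins all other terms."""
    X_all, _, _ = _build_design(table, terms)
    X_wo, _, _ = _build_design(table, [t for t in terms if t != term])
    return int(np.linalg.matrix_rank(X_all) - np.linalg.matrix_rank(X_wo))


# --------------------------------------------------------------------------
# Tukey-Kramer
# --------------------------------------------------------------------------

def tukey_kramer(fit: GlmFit, factor: str, n_mc: int = 200_000,
                 seed: int = 0) -> pd.DataFrame:
    """All pairwise comparisons of a factor's link-scale marginal means.

    Adjusted p-values use the single-step max-modulus distribution of the
    joint normal contrast vector (correlation from the coefficient
    covariance), evaluated by a seeded Monte-Carlo draw.
    """
    table = fit.table
    levels = sorted(pd.unique(table[factor].astype(str)))
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    X = fit.design_info["X"]
    beta = np.asarray(fit.result.params)
    cov = np.asarray(fit.result.cov_params())

    # marginal mean on the link scale: average design row per level
    L = np.stack([
        X[(table[factor].astype(str) == lv).to_numpy()].mean(axis=0)
        for lv in levels
    ])
    pairs = list(combinations(range(len(levels)), 2))
    C = np.stack([L[j] - L[i] for i, j in pairs])
    est = C @ beta
    V = C @ cov @ C.T
    se = np.sqrt(np.diag(V))
    t = est / se
    # joint null distribution of the standardized contrasts
    corr = V / np.outer(se, se)
    p_raw = 2 * stats.norm.sf(np.abs(t))
    if len(pairs) == 1:
        p_adj = p_raw.copy()
    else:
        rng = np.random.default_rng(seed)
        Z = rng.multivariate_normal(np.zeros(len(pairs)), corr, size=n_mc,
                                    method="eigh")
        maxmod = np.abs(Z).max(axis=1)
        p_adj = np.minimum(1.0, (np.abs(t)[None, :] <= maxmod[:, None]).mean(axis=0))
        p_adj = np.maximum(p_adj, p_raw)  # family-wise adjustment >= raw
    return pd.DataFrame({
        "contrast": [f"{levels[j]} - {levels[i]}" for i, j in pairs],
        "estimate": est, "se": se, "t": t, "p_raw": p_raw, "p_adj": p_adj,
    })


# --------------------------------------------------------------------------
# correlations, normality, ICC
# --------------------------------------------------------------------------

def phenotype_correlations(table: pd.DataFrame,
                           traits=("SL", "RL", "NOL", "NOB"),
                           groups=("G", "M", "E")):
    """Pairwise Pearson correlations with p-values, overall and per group.

    Returns a tidy DataFrame with columns group (``all`` for the pooled
    test), level, trait_a, trait_b, n, r, p.  Zero-variance columns yield
    NaN r with a warning entry rather than an error.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    rows = []

    def corr_block(sub, group, level):
        for a, b in combinations(traits, 2):
            x = sub[a].to_numpy(float)
            y = sub[b].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append({"group": group, "level": level, "trait_a": a,
                             "trait_b": b, "n": len(x), "r": np.nan,
                             "p": np.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"group": group, "level": level, "trait_a": a,
                         "trait_b": b, "n": len(x), "r": r, "p": p})

    corr_block(table, "all", "all")
    for g in groups:
        for level, sub in table.groupby(g):
            corr_block(sub, g, level)
    return pd.DataFrame(rows)


def shapiro_screen(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p for 3 <= n <= 5000 observations."""
    v = np.asarray(values, float)
    if not (3 <= len(v) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant sample")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def icc_pot(table: pd.DataFrame, response: str = "SL",
            pot_col: str = "pot") -> float:
    """One-way random-effects ICC of pots within one treatment combination.

    Method-of-moments: ICC = sigma2_between / (sigma2_between +
    sigma2_within), with negative between-pot estimates truncated to 0.
    """
    groups = [g[response].to_numpy(float) for _, g in table.groupby(pot_col)]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 pots")
    ns = np.array([len(g) for g in groups], float)
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (k - 1)
    dfw = N - k
    msw = ssw / dfw if dfw > 0 else 0.0
    n0 = (N - (ns ** 2).sum() / N) / (k - 1)
    sb2 = max(0.0, (msb - msw) / n0)
    denom = sb2 + msw
    return float(sb2 / denom) if denom > 0 else 0.0


def icc_all(table: pd.DataFrame, response: str = "SL",
            combo=("G", "M", "E"), pot_col: str = "pot") -> pd.DataFrame:
    """Pot ICC per treatment combination; combinations with one pot are
    skipped."""
    rows = []
    for key, sub in table.groupby(list(combo)):
        if sub[pot_col].nunique() < 2:
            continue
        rows.append(dict(zip(combo, key)) | {
            "ICC": icc_pot(sub, response, pot_col), "n": len(sub)})
    return pd.DataFrame(rows)
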
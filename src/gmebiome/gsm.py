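"""Per-OTU penalized nominal-kernel regression ("generalized smoothing
model") of bacterial frequency on G, M, E and their interactions, with
term-wise approximate F-tests and Fisher family-enrichment under BH-FDR.

For categorical factors the nominal reproducing kernel
k(a, b) = 1{a=b} - 1/L (tensor products for interactions) is equivalent to
a ridge penalty on sum-to-zero level effects, so each term contributes a
centered indicator block with its own smoothing parameter; the smoothing
parameters are selected by generalized cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from .synthetic_data import TERMS
from .taxonomy import NOT_ASSIGNED, OtuTable

__all__ = ["GsmFit", "EnrichmentRow", "filter_prevalent", "fit_gsm",
           "gsm_term_test", "family_enrichment", "gsm_screen"]


@dataclass
class GsmFit:
    """Fitted additive nominal-kernel smoother."""

    terms: tuple[str, ...]
    lambdas: dict[str, float]
    coefficients: dict[str, pd.Series]     # per-term level effects (sum 0)
    intercept: float
    fitted: np.ndarray
    rss: float
    edf: dict[str, float]                  # effective df per term
    edf_total: float
    n: int
    gcv: float
    design: dict = field(repr=False, default_factory=dict)


def filter_prevalent(table: OtuTable, min_individuals: int = 6) -> OtuTable:
    """Keep OTUs with nonzero counts in strictly more than
    ``min_individuals`` individuals."""
    if table.counts.empty:
        return table
    prev = (table.counts > 0).sum(axis=0)
    keep = table.counts.columns[prev > min_individuals]
    lin = table.lineages.loc[keep] if table.lineages is not None else None
    return OtuTable(counts=table.counts[keep].copy(), lineages=lin)


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _centered_onehot(labels: np.ndarray):
    levels = sorted(pd.unique(labels))
    L = len(levels)
    Z = (labels[:, None] == np.array(levels)[None, :]).astype(float) - 1.0 / L
    return Z, levels


def _term_design(metadata: pd.DataFrame, term: str):
    """Tensor product of centered one-hot blocks: the nominal-kernel basis.

    Column (l1, .., lk) at row i is prod_f (1{x_if = lf} - 1/L_f); the term
    function is orthogonal to lower-order terms in balanced designs and its
    level effects sum to zero over each margin.
    """
    factors = term.split("x")
    Z, levels = _centered_onehot(metadata[factors[0]].astype(str).to_numpy())
    names = [(lv,) for lv in levels]
    for f in factors[1:]:
        Z2, lv2 = _centered_onehot(metadata[f].astype(str).to_numpy())
        Z = np.einsum("ij,ik->ijk", Z, Z2).reshape(len(Z), -1)
        names = [n + (lv,) for n in names for lv in lv2]
    labels = [":".join(n) for n in names]
    return Z, labels


def _assemble(metadata: pd.DataFrame, terms):
    blocks, labels, slices = [], {}, {}
    pos = 0
    for term in terms:
        Z, names = _term_design(metadata, term)
        for f in term.split("x"):
            if metadata[f].nunique() < 2:
                raise ValueError(f"factor {f} has a single represented level")
        blocks.append(Z)
        labels[term] = names
        slices[term] = slice(pos, pos + Z.shape[1])
        pos += Z.shape[1]
    return np.hstack(blocks), labels, slices


def _solve(y, Z, slices, lambdas, terms):
    """Penalized LS: minimize ||y - b0 - Z a||^2 + sum_t lam_t ||a_t||^2."""
    n, p = Z.shape
    pen = np.zeros(p)
    for t in terms:
        pen[slices[t]] = lambdas[t]
    yc = y - y.mean()
    A = Z.T @ Z + np.diag(pen)
    coef = np.linalg.solve(A, Z.T @ yc)
    fitted = y.mean() + Z @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    # effective df: trace of the hat matrix contribution per term
    Ainv = np.linalg.inv(A)
    H_diag_blocks = Ainv @ (Z.T @ Z)
    edf = {t: float(np.trace(H_diag_blocks[slices[t], slices[t]]))
           for t in terms}
    edf_total = 1.0 + sum(edf.values())
    return coef, fitted, rss, edf, edf_total


def fit_gsm(frequency, metadata: pd.DataFrame, terms=TERMS,
            lambdas: dict[str, float] | None = None,
            logit: bool = False) -> GsmFit:
    """Fit the additive nominal-kernel smoother for one OTU's frequency.

    With ``lambdas`` given they are used as-is; otherwise per-term
    smoothing parameters are selected by minimizing the GCV score
    n * RSS / (n - edf)^2 over log-lambda.
    """
    y = np.asarray(frequency, float)
    if len(y) != len(metadata):
        raise ValueError("frequency vector must align with metadata")
    if logit:
        eps = 1e-6
        y = np.log((y + eps) / (1 - y + eps))
    terms = tuple(terms)
    Z, labels, slices = _assemble(metadata, terms)
    n = len(y)

    if np.allclose(y, y[0]):
        lambdas = lambdas or {t: 1.0 for t in terms}
        coef = np.zeros(Z.shape[1])
        edf = {t: 0.0 for t in terms}
        return GsmFit(terms=terms, lambdas=dict(lambdas),
                      coefficients=_per_term(coef, labels, slices, terms),
                      intercept=float(y.mean()), fitted=np.full(n, y.mean()),
                      rss=0.0, edf=edf, edf_total=1.0, n=n, gcv=0.0,
                      design={"Z": Z, "slices": slices, "labels": labels,
                              "y": y, "metadata": metadata})

    if lambdas is None:
        # log-lambda kept in a bounded box: the lower bound is effectively
        # the unpenalized fit, the upper effectively removes the term
        lo, hi = -8.0, 16.0

        def gcv_of(logl):
            lam = {t: float(np.exp(np.clip(v, lo, hi)))
                   for t, v in zip(terms, logl)}
            _, _, rss, _, edf_tot = _solve(y, Z, slices, lam, terms)
            denom = max(n - edf_tot, 1e-6)
            return n * rss / denom ** 2

        best = None
        for x0 in (np.zeros(len(terms)), np.full(len(terms), np.log(10.0))):
            res = minimize(gcv_of, x0, method="Nelder-Mead",
                           options={"maxiter": 200 * len(terms),
                                    "xatol": 1e-2, "fatol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        lambdas = {t: float(np.exp(np.clip(v, lo, hi)))
                   for t, v in zip(terms, best.x)}
    lambdas = {t: max(float(lambdas[t]), 1e-8) for t in terms}

    coef, fitted, rss, edf, edf_total = _solve(y, Z, slices, lambdas, terms)
    denom = max(n - edf_total, 1e-6)
    return GsmFit(terms=terms, lambdas=lambdas,
                  coefficients=_per_term(coef, labels, slices, terms),
                  intercept=float(y.mean()), fitted=fitted, rss=rss,
                  edf=edf, edf_total=edf_total, n=n,
                  gcv=float(n * rss / denom ** 2),
                  design={"Z": Z, "slices": slices, "labels": labels,
                          "y": y, "metadata": metadata})


def _per_term(coef, labels, slices, terms):
    out = {}
    for t in terms:
        a = coef[slices[t]]
        out[t] = pd.Series(a - a.mean(), index=labels[t])
    return out


def gsm_term_test(fit: GsmFit, term: str) -> tuple[float, float]:
    """Approximate F-test of one term: full fit vs fit without the term.

    Other terms keep their selected smoothing parameters.  Numerator df is
    the effective-df difference (rounded to 2 decimals); denominator df is
    n - edf of the full model.
    """
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in fitted model")
    reduced_terms = tuple(t for t in fit.terms if t != term)
    y = fit.design["y"]
    meta = fit.design["metadata"]
    if reduced_terms:
        lam = {t: fit.lambdas[t] for t in reduced_terms}
        red = fit_gsm(y, meta, terms=reduced_terms, lambdas=lam)
        rss0, edf0 = red.rss, red.edf_total
    else:
        rss0 = float(((y - y.mean()) ** 2).sum())
        edf0 = 1.0
    df_num = round(fit.edf_total - edf0, 2)
    df_den = fit.n - fit.edf_total
    if df_num <= 0 or df_den <= 0 or fit.rss <= 0:
        return 0.0, 1.0
    F = ((rss0 - fit.rss) / df_num) / (fit.rss / df_den)
    F = max(F, 0.0)
    return float(F), float(stats.f.sf(F, df_num, df_den))


def gsm_screen(otu_table: OtuTable, metadata: pd.DataFrame, terms=TERMS,
               alpha: float = 0.05, logit: bool = False) -> pd.DataFrame:
    """Fit the smoother per OTU and test every term; tidy results table.

    Frequencies are per-sample proportions of the count table.  Returns
    columns otu, term, F, p, significant (p < alpha).
    """
    counts = otu_table.counts
    freq = counts.div(counts.sum(axis=1), axis=0).fillna(0.0)
    rows = []
    for otu in counts.columns:
        fit = fit_gsm(freq[otu].to_numpy(), metadata, terms=terms, logit=logit)
        for term in terms:
            F, p = gsm_term_test(fit, term)
            rows.append({"otu": otu, "term": term, "F": F, "p": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    family: str
    k_sig: int
    k_total: int
    n_sig: int
    n_total: int
    odds_ratio: float
    p: float
    fdr_p: float
    flagged: bool


def family_enrichment(families: dict[str, str] | pd.Series,
                      significant: set | list,
                      alpha_fdr: float = 0.05) -> list[EnrichmentRow]:
    """Fisher exact family enrichment of a significant OTU set with BH-FDR.

    ``families`` maps OTU id -> family name (NotAssigned bins allowed as
    their own families); ``significant`` is the set of significant OTU ids.
    """
    fam = pd.Series(dict(families))
    sig = set(significant)
    n_total = len(fam)
    n_sig = len(sig & set(fam.index))
    rows = []
    for family in sorted(fam.unique()):
        members = set(fam.index[fam == family])
        k_total = len(members)
        k_sig = len(members & sig)
        table = [[k_sig, n_sig - k_sig],
                 [k_total - k_sig, (n_total - n_sig) - (k_total - k_sig)]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append([family, k_sig, k_total, n_sig, n_total, odds, p])
    pvals = [r[-1] for r in rows]
    if pvals:
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        fdr = []
    return [EnrichmentRow(*r, fdr_p=float(q), flagged=bool(q < alpha_fdr))
            for r, q in zip(rows, fdr)]
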
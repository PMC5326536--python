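"""Correlation and regression machinery for windowed diversity.

Spearman rank correlation (midranks; exact permutation p for tiny n),
ordinary least squares with classical inference (via statsmodels), principal
component regression on the predictor correlation matrix, the
chromosome-length covariate model, and decile-stratified diversity ~
recombination fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import floor
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float


@dataclass
class RegressionResult:
    params: pd.DataFrame  # index: term; columns: coef, se, t, p
    r2: float
    f_stat: float
    df_model: int
    df_resid: int
    f_pvalue: float
    n: int

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])

    def t(self, term: str) -> float:
        return float(self.params.loc[term, "t"])

    def p(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


@dataclass
class PCRResult:
    loadings: pd.DataFrame        # predictors x PCs (orthonormal columns)
    eigenvalues: np.ndarray
    predictor_variance_share: np.ndarray
    response_r2: np.ndarray       # per-PC share of response variance
    association_sign: np.ndarray  # sign of corr(y, PC score)
    n: int

    @property
    def total_r2(self) -> float:
        return float(self.response_r2.sum())


def _complete(*arrays):
    cols = [np.asarray(a, dtype=np.float64) for a in arrays]
    ok = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        ok &= np.isfinite(c) if c.ndim == 1 else np.isfinite(c).all(axis=1)
    return [c[ok] for c in cols], ok


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    rho is the Pearson correlation of the midranks; the p-value uses the
    exact permutation distribution for n ≤ 8 and the t approximation
    otherwise.
    """
    (x, y), _ = _complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx, ry = st.rankdata(x), st.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant input to spearman")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc ** 2).sum())
        hits = 0
        total = 0
        for perm in permutations(ry):
            r = float(np.dot(rxc, perm)) / (denom * np.sqrt(
                ((np.asarray(perm) - ry.mean()) ** 2).sum()))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * st.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, n, p)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns that are (numerically) linear combinations of earlier ones."""
    bad = []
    M = X.to_numpy(dtype=np.float64)
    kept: list[int] = []
    for j in range(M.shape[1]):
        cand = M[:, kept + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) <= len(kept):
            bad.append(X.columns[j])
        else:
            kept.append(j)
    return bad


def ols(y, X: pd.DataFrame) -> RegressionResult:
    """OLS with intercept, classical SEs, t, two-sided p, R² and overall F.

    Complete cases only; a rank-deficient design raises an error naming the
    collinear columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=np.float64)).all(axis=1)
    Xc, yc = X[ok], y[ok]
    n, p = Xc.shape
    if n <= p + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p} predictors")
    design = sm.add_constant(Xc.to_numpy(dtype=np.float64), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    fit = sm.OLS(yc, design).fit()
    terms = ["const"] + list(Xc.columns)
    params = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
        index=terms,
    )
    return RegressionResult(
        params=params, r2=float(fit.rsquared), f_stat=float(fit.fvalue),
        df_model=int(fit.df_model), df_resid=int(fit.df_resid),
        f_pvalue=float(fit.f_pvalue), n=n,
    )


def pcr(y, X: pd.DataFrame, eig_tol: float = 1e-10) -> PCRResult:
    """Principal component regression on the predictor correlation matrix.

    Predictors are standardised on complete cases; PCs come from the
    eigendecomposition of their correlation matrix, oriented so each PC's
    largest-magnitude loading is positive. Because PC scores are mutually
    uncorrelated, the response variance splits additively: the per-PC R²
    (squared correlation of y with the score) sums to the OLS R² on the same
    cases. Near-zero eigenvalue PCs carry no variance and get R² 0. The sign
    of each PC's association with y is reported separately.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=np.float64)).all(axis=1)
    Xc = X[ok].to_numpy(dtype=np.float64)
    yc = y[ok]
    n, p = Xc.shape
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [X.columns[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant predictor(s): {const}")
    Z = (Xc - Xc.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # orient: largest-|loading| entry positive
    for k in range(p):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = Z @ evecs
    yc_c = yc - yc.mean()
    ssy = float((yc_c ** 2).sum())
    r2 = np.zeros(p)
    sign = np.zeros(p)
    for k in range(p):
        if evals[k] <= eig_tol:
            continue
        s = scores[:, k]
        cov = float(s @ yc_c)
        sss = float((s ** 2).sum())
        r2[k] = cov * cov / (sss * ssy)
        sign[k] = np.sign(cov)
    loadings = pd.DataFrame(evecs, index=list(X.columns),
                            columns=[f"PC{k + 1}" for k in range(p)])
    return PCRResult(
        loadings=loadings, eigenvalues=evals,
        predictor_variance_share=evals / evals.sum(),
        response_r2=r2, association_sign=sign, n=n,
    )


def chromosome_covariate_model(
    pi_b, pi_a, chrom_length, log_length: bool = False
) -> RegressionResult:
    """Does chromosome length add anything beyond the other species' diversity?

    OLS of species-B window diversity on species-A diversity and chromosome
    length (optionally log10-transformed).
    """
    (pb, pa, cl), _ = _complete(pi_b, pi_a, chrom_length)
    if len(pb) < 4:
        raise ValueError("need at least 4 complete windows")
    length = np.log10(cl) if log_length else cl
    X = pd.DataFrame({"pi_other": pa, "chrom_length": length})
    return ols(pb, X)


def decile_stratified_regression(
    pi, rec, stratifier, decile: str, fraction: float = 0.10,
    tiebreak: Optional[Sequence] = None,
) -> RegressionResult:
    """Diversity ~ recombination within an extreme stratum of another variable.

    Picks the floor(fraction·n) complete-case windows with the highest or
    lowest stratifier value (ties broken by window coordinate when supplied,
    else by input order) and fits OLS of π on the (already transformed)
    recombination rate inside the stratum.
    """
    if decile not in ("lowest", "highest"):
        raise ValueError("decile must be 'lowest' or 'highest'")
    (pi_c, rec_c, strat_c), ok = _complete(pi, rec, stratifier)
    n = len(pi_c)
    m = floor(fraction * n)
    if m < 3:
        raise ValueError(f"stratum too small: floor({fraction}*{n}) = {m}")
    if np.all(strat_c == strat_c[0]):
        raise ValueError("constant stratifier: deciles are undefined")
    if tiebreak is not None:
        tb = np.asarray(tiebreak)[ok]
        order = np.lexsort((tb, strat_c))
    else:
        order = np.argsort(strat_c, kind="stable")
    idx = order[:m] if decile == "lowest" else order[-m:]
    return ols(pi_c[idx], pd.DataFrame({"rec": rec_c[idx]}))
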
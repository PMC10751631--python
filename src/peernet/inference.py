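"""Ordinary least squares with t-based intervals and covariate screening.

The scientific question is a group contrast: does holding a designated,
trained leader role predict higher mean relative centrality, adjusting for
demographics?  The estimator is plain OLS — coefficients from the normal
equations, 95% confidence intervals from the t distribution on n - p
residual degrees of freedom, two-sided p-values.

Covariates enter through a two-stage screen: a candidate joins the
multivariable model if its univariate association with the outcome has
p <= 0.25, and is dropped (single pass) if its multivariable p exceeds
0.05.  The primary term is always retained.  Multi-column candidates
(categorical blocks) are screened with partial F-tests, which for a single
column coincide with the two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "ScreeningRule",
    "RankDeficientError",
    "fit_ols",
    "screen_and_fit",
    "encode_categorical",
]


class RankDeficientError(ValueError):
    """Design matrix is not full column rank; message names suspect terms."""


@dataclass(frozen=True)
class ScreeningRule:
    univariate_alpha: float = 0.25
    multivariable_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.multivariable_alpha <= self.univariate_alpha < 1):
            raise ValueError(
                "require 0 < multivariable_alpha <= univariate_alpha < 1"
            )


@dataclass
class RegressionResult:
    terms: list
    coefficients: dict
    se: dict
    ci_95: dict
    p_values: dict
    n: int
    df_resid: int
    sigma2: float
    rss: float
    zero_residual_variance: bool = False
    screening: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coefficients": self.coefficients,
            "se": self.se,
            "ci_95": {k: list(v) for k, v in self.ci_95.items()},
            "p_values": self.p_values,
            "n": self.n,
            "df_resid": self.df_resid,
            "sigma2": self.sigma2,
            "zero_residual_variance": self.zero_residual_variance,
            "screening": self.screening,
        }


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name columns whose removal restores full rank among the rest
        suspects = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == r:
                suspects.append(terms[j])
        raise RankDeficientError(
            f"design matrix rank {r} < {X.shape[1]} columns; "
            f"collinear terms: {suspects or list(terms)}"
        )


def fit_ols(outcome: np.ndarray, design: np.ndarray, terms: Sequence[str]) -> RegressionResult:
    """Least-squares fit with t-based 95% CIs and two-sided p-values.

    ``design`` must include its intercept column explicitly (conventionally
    named "intercept").  Zero residual variance (an exact fit or constant
    outcome) is flagged; there the p-value convention is 1 for a zero
    coefficient and 0 otherwise.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("outcome and design row counts differ")
    n, p = X.shape
    if len(terms) != p:
        raise ValueError("terms must name every design column")
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    _check_rank(X, terms)

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))

    zero_var = sigma2 <= max(1.0, float(y @ y)) * 1e-14
    tcrit = float(stats.t.ppf(0.975, df))
    coef, ses, cis, ps = {}, {}, {}, {}
    for j, name in enumerate(terms):
        b = float(beta[j])
        s = float(se[j])
        coef[name] = b
        ses[name] = s
        cis[name] = (b - tcrit * s, b + tcrit * s)
        if zero_var or s == 0.0:
            ps[name] = 1.0 if abs(b) < 1e-12 else 0.0
        else:
            ps[name] = float(2 * stats.t.sf(abs(b) / s, df))
    return RegressionResult(
        terms=list(terms),
        coefficients=coef,
        se=ses,
        ci_95=cis,
        p_values=ps,
        n=n,
        df_resid=df,
        sigma2=sigma2,
        rss=rss,
        zero_residual_variance=bool(zero_var),
    )


def _block_p(y: np.ndarray, X_reduced: np.ndarray, block: np.ndarray) -> float:
    """Partial F-test p-value for adding ``block`` to ``X_reduced``."""
    y = np.asarray(y, dtype=float).ravel()
    X_full = np.column_stack([X_reduced, block])
    n = y.shape[0]
    q = block.shape[1]
    df_full = n - X_full.shape[1]
    if df_full <= 0:
        raise ValueError("insufficient residual degrees of freedom for F-test")
    beta_r, _, _, _ = np.linalg.lstsq(X_reduced, y, rcond=None)
    beta_f, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_r = float(np.sum((y - X_reduced @ beta_r) ** 2))
    rss_f = float(np.sum((y - X_full @ beta_f) ** 2))
    if rss_f <= max(1.0, float(y @ y)) * 1e-14:
        return 1.0 if rss_r - rss_f <= 1e-12 else 0.0
    F = ((rss_r - rss_f) / q) / (rss_f / df_full)
    return float(stats.f.sf(max(F, 0.0), q, df_full))


def _as_block(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return a.reshape(-1, 1) if a.ndim == 1 else a


def screen_and_fit(
    outcome: np.ndarray,
    primary_term: tuple,
    candidates: Mapping[str, object],
    rule: ScreeningRule = ScreeningRule(),
    candidate_columns: Optional[Mapping[str, Sequence[str]]] = None,
) -> RegressionResult:
    """Fit the primary model with screened covariates.

    ``primary_term`` is ``(name, vector)`` — typically the leader indicator
    — and is always retained.  ``candidates`` maps name -> vector or
    (n, k) block; ``candidate_columns`` optionally names a block's columns
    in the final report.  The screening audit trail is recorded on the
    result.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.shape[0]
    ones = np.ones((n, 1))
    pname, pvec = primary_term
    pblock = _as_block(pvec)

    audit: dict = {}
    stage1 = []
    for name, v in candidates.items():
        block = _as_block(v)
        p_uni = _block_p(y, ones, block)
        entered = p_uni <= rule.univariate_alpha
        audit[name] = {"univariate_p": p_uni, "entered_multivariable": entered}
        if entered:
            stage1.append((name, block))

    kept = stage1
    if stage1:
        base = np.column_stack([ones, pblock])
        drop = []
        for name, block in stage1:
            others = [b for nm, b in stage1 if nm != name]
            X_red = np.column_stack([base] + others) if others else base
            p_multi = _block_p(y, X_red, block)
            audit[name]["multivariable_p"] = p_multi
            if p_multi > rule.multivariable_alpha:
                drop.append(name)
                audit[name]["retained"] = False
            else:
                audit[name]["retained"] = True
        kept = [(nm, b) for nm, b in stage1 if nm not in drop]

    terms = ["intercept", pname]
    cols = [ones, pblock]
    for nm, b in kept:
        names = (
            list(candidate_columns[nm])
            if candidate_columns and nm in candidate_columns
            else ([nm] if b.shape[1] == 1 else [f"{nm}[{j}]" for j in range(b.shape[1])])
        )
        terms.extend(names)
        cols.append(b)
    X = np.column_stack(cols)
    result = fit_ols(y, X, terms)
    result.screening = audit
    return result


def encode_categorical(values: Sequence[str], reference: Optional[str] = None) -> tuple:
    """Reference-level indicator coding; reference = most frequent level.

    Returns ``(matrix, column_names, reference_level)``; missing-style
    levels are ordinary levels, matching a roster where "missing" is an
    explicit category.
    """
    vals = [str(v) for v in values]
    levels, counts = np.unique(vals, return_counts=True)
    if reference is None:
        reference = str(levels[np.argmax(counts)])
    others = [lv for lv in levels if lv != reference]
    mat = np.column_stack([[1.0 if v == lv else 0.0 for v in vals] for lv in others]) if others else np.empty((len(vals), 0))
    return mat, [f"[{lv}]" for lv in others], reference
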
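"""Regression models linking neurochemistry to BOLD hemodynamics.

Seven ordinary-least-squares models relate a BOLD response variable
(HRF amplitude / time-to-peak / FWHM or a segment's Z(AUC)) to GABA+, Glx,
and age: the three single-predictor models, the three two-way
predictor-by-predictor models, and the full three-way model.  Interaction
products are formed from mean-centered main effects; fits are ranked by
adjusted R^2.  Companion utilities compute the pooled two-sample t and
Cohen's d, the noncentral-t power-based per-group sample size, the
Bonferroni threshold, and the F statistic implied by an R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MODEL_TERMS",
    "ModelFit",
    "fit_model_suite",
    "group_difference",
    "group_difference_from_summary",
    "power_sample_size",
    "power_two_sample_t",
    "bonferroni_alpha",
    "regression_f_from_r2",
]

# The fixed 7-model set: name -> predictor terms (products written "a:b").
MODEL_TERMS: dict[str, list[str]] = {
    "Glx-only": ["Glx"],
    "GABA-only": ["GABA"],
    "GABA-by-Glx": ["Glx", "GABA", "GABA:Glx"],
    "Age-only": ["Age"],
    "Age-by-Glx": ["Glx", "Age", "Age:Glx"],
    "Age-by-GABA": ["GABA", "Age", "Age:GABA"],
    "Age-by-Glx-by-GABA": [
        "Glx", "GABA", "Age", "GABA:Glx", "GABA:Age", "Glx:Age",
    ],
}

SIGNIFICANT_P = 0.01     # study convention: significant at p <= 0.01,
TRENDING_P = 0.05        # trending at 0.01 < p < 0.05


@dataclass
class ModelFit:
    name: str
    response: str
    params: pd.DataFrame         # term, beta, t, p, flag
    fvalue: float
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    nobs: int

    @property
    def flag(self) -> str:
        return _flag(self.f_pvalue)


def _flag(p: float) -> str:
    if p <= SIGNIFICANT_P:
        return "significant"
    if p < TRENDING_P:
        return "trending"
    return "ns"


def _design(table: pd.DataFrame, terms: list[str], center: bool) -> pd.DataFrame:
    cols = {}
    centered = {}
    for v in ("GABA", "Glx", "Age"):
        if v in table:
            x = table[v].astype(float)
            centered[v] = x - x.mean() if center else x
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols[term] = centered[a] * centered[b]
        else:
            cols[term] = centered[term]
    X = pd.DataFrame(cols, index=table.index)
    return sm.add_constant(X)


def fit_model_suite(
    table: pd.DataFrame,
    response: str,
    center: bool = True,
    models: dict[str, list[str]] | None = None,
) -> list[ModelFit]:
    """Fit all seven models for one response and rank by adjusted R^2.

    Continuous predictors are mean-centered before interaction products
    are formed (reduces collinearity; matches standard least-squares
    practice for polynomial/cross terms).  Raises on missing responses,
    insufficient sample size, or a collinear design (naming the terms).
    """
    models = models or MODEL_TERMS
    if response not in table:
        raise ValueError(f"response {response!r} not in table")
    y = table[response].astype(float)
    if y.isna().any():
        raise ValueError(f"missing values in response {response!r}")
    fits = []
    for name, terms in models.items():
        X = _design(table, terms, center)
        if len(table) < X.shape[1] + 1:
            raise ValueError(
                f"{name}: n={len(table)} too small for {X.shape[1]} terms"
            )
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"{name}: collinear design among {list(X)}")
        res = sm.OLS(y, X).fit()
        params = pd.DataFrame(
            {
                "term": X.columns,
                "beta": res.params.to_numpy(),
                "t": res.tvalues.to_numpy(),
                "p": res.pvalues.to_numpy(),
            }
        )
        params["flag"] = params["p"].map(_flag)
        fits.append(
            ModelFit(
                name=name,
                response=response,
                params=params,
                fvalue=float(res.fvalue),
                f_pvalue=float(res.f_pvalue),
                rsquared=float(res.rsquared),
                rsquared_adj=float(res.rsquared_adj),
                nobs=int(res.nobs),
            )
        )
    fits.sort(key=lambda f: f.rsquared_adj, reverse=True)
    return fits


# ---------------------------------------------------------------------------
# group differences
# ---------------------------------------------------------------------------

def group_difference_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> dict[str, float]:
    """Pooled-variance two-sample t, p, and Cohen's d from group summaries."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    sp = math.sqrt(sp2)
    se = sp * math.sqrt(1.0 / n_a + 1.0 / n_b)
    t = (mean_a - mean_b) / se
    df = n_a + n_b - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    d = (mean_a - mean_b) / sp
    return {"t": t, "p": p, "d": d, "df": df}


def group_difference(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> dict[str, float]:
    """Two-sample t-test with pooled Cohen's d.

    Pooled-variance t by default (the study's convention); Welch's t by
    flag (d is still reported against the pooled SD).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not welch:
        return group_difference_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return {
        "t": float(t), "p": float(p),
        "d": float((a.mean() - b.mean()) / math.sqrt(sp2)),
        "df": float(len(a) + len(b) - 2),
    }


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def power_two_sample_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at per-group n and effect
    size d, under the noncentral-t distribution."""
    df = 2 * n - 2
    if df < 1:
        return 0.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * math.sqrt(n / 2.0)
    return float(
        stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
    )


def power_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 100000
) -> int:
    """Smallest per-group n with two-sided two-sample t-test power >= the
    target at effect size d (noncentral-t; power(n) >= target > power(n-1))."""
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    for n in range(2, n_max + 1):
        if power_two_sample_t(n, d, alpha) >= power:
            return n
    raise ValueError("no adequate n found below n_max")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def regression_f_from_r2(r2: float, n: int, p: int = 1) -> float:
    """Whole-model F implied by R^2 with p predictors and n observations:
    F = (R^2/p) / ((1 - R^2)/(n - p - 1))."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))
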
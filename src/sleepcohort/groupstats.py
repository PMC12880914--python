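"""Group-difference statistics with family structure.

Sibling designs induce within-family correlation: both children share a
household (and half their genome), so observations are not exchangeable
across families. Group contrasts therefore use a linear mixed model with a
random intercept per family and diagnosis, age and sex as fixed effects,
fit by REML through statsmodels' MixedLM. From the fit we report:

* the intraclass correlation ICC = σ²_between / (σ²_between + σ²_within),
  the share of outcome variance explained by family membership;
* Cohen's f² for the diagnosis predictor,
  f² = (R²_full − R²_reduced) / (1 − R²_full), with R² the marginal
  (fixed-effects) variance-explained proportion — the added variance
  explained when diagnosis enters the model.

Plain two-sample Welch t tests (with Cohen's d) and χ² proportion tests
cover the unpaired benchmark comparisons.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .dtypes import MixedModelResult


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed to converge; carries fit diagnostics."""


def fit_family_lmm(table: pd.DataFrame, outcome: str,
                   fixed: Sequence[str] = ("diagnosis", "age", "sex"),
                   group: str = "family_id",
                   compute_f2: bool = True,
                   f2_predictor: str = "diagnosis",
                   conditional_r2: bool = False) -> MixedModelResult:
    """REML fit of ``outcome ~ fixed effects + (1 | family)``.

    Data may be per-night (sleep measures; repeated rows per child) or
    per-child (questionnaires). Deterministic given the data. Raises
    :class:`ConvergenceError` on a failed fit and ValueError with fewer
    than two families.
    """
    df = table.dropna(subset=[outcome, group, *fixed]).copy()
    if df[group].nunique() < 2:
        raise ValueError("mixed model requires at least 2 families")
    # stable coding: diagnosis autism=1 vs sibling=0, sex M=1 vs F=0
    terms = []
    for f in fixed:
        if f == "diagnosis":
            df["dx"] = (df["diagnosis"] == "autism").astype(float)
            terms.append("dx")
        elif f == "sex":
            df["male"] = (df["sex"] == "M").astype(float)
            terms.append("male")
        else:
            terms.append(f)
    formula = f"{outcome} ~ " + " + ".join(terms) if terms else f"{outcome} ~ 1"

    res = _fit(formula, df, group)
    sigma2_b = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    sigma2_w = float(res.scale)
    icc_val = sigma2_b / (sigma2_b + sigma2_w) if (sigma2_b + sigma2_w) > 0 else 0.0

    r2_full = _marginal_r2(res, df, outcome, conditional=conditional_r2)
    f2 = None
    key = "dx" if f2_predictor == "diagnosis" else f2_predictor
    if compute_f2 and key in terms:
        reduced_terms = [t for t in terms if t != key]
        red_formula = (f"{outcome} ~ " + " + ".join(reduced_terms)
                       if reduced_terms else f"{outcome} ~ 1")
        red = _fit(red_formula, df, group)
        r2_red = _marginal_r2(red, df, outcome, conditional=conditional_r2)
        f2 = max((r2_full - r2_red) / max(1.0 - r2_full, 1e-12), 0.0)

    names = list(res.fe_params.index)
    return MixedModelResult(
        outcome=outcome,
        params={n: float(res.fe_params[n]) for n in names},
        bse={n: float(res.bse_fe[n]) for n in names},
        pvalues={n: float(res.pvalues[n]) for n in names},
        sigma2_between=sigma2_b,
        sigma2_within=sigma2_w,
        icc=icc_val,
        f2_diagnosis=f2,
        n_obs=int(res.nobs),
        n_groups=int(df[group].nunique()),
        converged=bool(res.converged),
        marginal_r2=r2_full,
    )


def _fit(formula: str, df: pd.DataFrame, group: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[group])
        res = None
        last_exc: Exception | None = None
        for method in (None, "powell", "nm"):
            try:
                kw = {} if method is None else {"method": method}
                res = model.fit(reml=True, **kw)
                if res.converged:
                    break
            except Exception as exc:  # singular/boundary fits
                last_exc = exc
        if res is None:
            raise ConvergenceError(f"mixed model fit failed: {last_exc}") from last_exc
    if not res.converged:
        raise ConvergenceError(
            f"mixed model did not converge for '{formula}' "
            f"(n={int(res.nobs)}, groups={df[group].nunique()})")
    return res


def _marginal_r2(res, df: pd.DataFrame, outcome: str,
                 conditional: bool = False) -> float:
    """Variance-explained proportion: var(Xβ) over total model variance.

    Marginal: var(Xβ) / (var(Xβ) + σ²_b + σ²_w). Conditional adds σ²_b to
    the numerator (variance explained by fixed + random effects).
    """
    fitted_fixed = np.asarray(res.model.exog) @ np.asarray(res.fe_params)
    var_f = float(np.var(fitted_fixed))
    sigma2_b = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    sigma2_w = float(res.scale)
    total = var_f + sigma2_b + sigma2_w
    if total <= 0:
        return 0.0
    num = var_f + (sigma2_b if conditional else 0.0)
    return num / total


def icc(sigma2_between: float, sigma2_within: float) -> float:
    """Between-family variance share of total variance."""
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_between + sigma2_within
    return sigma2_between / tot if tot > 0 else 0.0


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """f² = (R²_full − R²_reduced) / (1 − R²_full), floored at 0."""
    if not (0 <= r2_reduced <= 1 and 0 <= r2_full <= 1):
        raise ValueError("R² values must lie in [0, 1]")
    if r2_full >= 1:
        raise ValueError("R²_full must be < 1")
    return max((r2_full - r2_reduced) / (1.0 - r2_full), 0.0)


def welch_t(x, y) -> dict:
    """Welch's unequal-variance t test plus Cohen's d (pooled-SD form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    denom = np.sqrt((vx + vy) / 2.0)
    d = (x.mean() - y.mean()) / denom if denom > 0 else 0.0
    return {"t": float(t), "df": float(df), "p": float(p),
            "cohens_d": float(d)}


def chi2_proportions(table, correction: bool = True) -> dict:
    """Pearson χ² on a 2×2 count table (Yates correction by default).

    Both corrected and uncorrected statistics are returned so the
    convention in any downstream report is explicit.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    chi2_c, p_c, _, _ = stats.chi2_contingency(obs, correction=True)
    chi2_u, p_u, _, _ = stats.chi2_contingency(obs, correction=False)
    if correction:
        return {"chi2": float(chi2_c), "p": float(p_c),
                "chi2_uncorrected": float(chi2_u), "p_uncorrected": float(p_u)}
    return {"chi2": float(chi2_u), "p": float(p_u),
            "chi2_corrected": float(chi2_c), "p_corrected": float(p_c)}


def bonferroni(p_values, m: Optional[int] = None, alpha: float = 0.05
               ) -> np.ndarray:
    """Significance flags at the Bonferroni-adjusted threshold α/m."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return p < alpha / m
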
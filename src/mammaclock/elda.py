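"""Limiting-dilution frequency estimation under the single-hit Poisson model.

Each transplanted well receives ``dose`` cells and regenerates an outgrowth
with probability 1 - exp(-f * dose), where f is the per-cell repopulating-
unit frequency.  This is a binomial GLM with complementary log-log link,
offset log(dose) and slope fixed at 1; the intercept is beta = log f.  The
MLE of beta is found by Newton iteration on the closed-form score and a Wald
95% CI on the log scale is inverted to the conventional "1 in N (lower -
upper)" report.  All-negative or all-positive tables sit on the boundary of
the parameter space and are reported with a one-sided exact bound instead of
a point estimate.  Groups are compared by a likelihood-ratio chi-square test
of pooled versus per-group frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

_Z95 = 1.959963984540054


@dataclass
class FrequencyEstimate:
    """Fitted repopulating-unit frequency with a 95% CI on 'cells per unit'."""

    frequency: float  # f-hat, per cell; 0.0 or inf at the boundary
    one_in: float  # 1 / f-hat
    ci_one_in: tuple[float, float]  # (lower N, upper N); N smaller = more frequent
    log_likelihood: float
    boundary: bool
    n_doses: int

    def __str__(self) -> str:  # conventional report
        lo, hi = self.ci_one_in
        if self.boundary:
            return f"boundary fit: 1 in {self.one_in:.4g} (95% bound {lo:.4g}-{hi:.4g})"
        return f"1 in {self.one_in:.1f} (95% CI {lo:.1f}-{hi:.1f})"


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    req = {"dose", "tested", "positive"}
    if not req.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(req)}")
    if (table["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    if ((table["positive"] < 0) | (table["positive"] > table["tested"])).any():
        raise ValueError("positive counts must lie in [0, tested]")
    return table


def _loglik(beta: float, dose, tested, positive) -> float:
    """Binomial log-likelihood at f = exp(beta) (terms without the constant)."""
    lam = np.exp(beta) * dose
    p = -np.expm1(-lam)  # 1 - exp(-lam), stable for small lam
    p = np.clip(p, 1e-300, 1.0)
    neg = tested - positive
    return float((positive * np.log(p) - neg * lam).sum())


def _score_info(beta: float, dose, tested, positive) -> tuple[float, float]:
    """First derivative and observed information of the log-likelihood."""
    lam = np.exp(beta) * dose
    elam = np.exp(-lam)
    p = -np.expm1(-lam)
    p = np.clip(p, 1e-300, 1.0)
    neg = tested - positive
    # d loglik / d beta; note d lam / d beta = lam
    score = float((positive * lam * elam / p - neg * lam).sum())
    # second derivative
    d2 = positive * (lam * elam / p) * (1.0 - lam - lam * elam / p) - neg * lam
    return score, float(-d2.sum())


def fit_frequency(table: pd.DataFrame, profile_ci: bool = False) -> FrequencyEstimate:
    """MLE of the single-hit frequency from one group's dose-response table.

    ``table`` has columns (dose, tested, positive); one row per dose level.
    A single dose level triggers a warning (the closed-form MLE is still
    exact).  With every well negative (or positive) the MLE sits at the
    boundary: frequency 0 (or indistinguishable from 1 per cell) and an
    exact one-sided 95% bound is reported in ``ci_one_in``.
    """
    table = _validate(table)
    dose = table["dose"].to_numpy(dtype=float)
    tested = table["tested"].to_numpy(dtype=float)
    positive = table["positive"].to_numpy(dtype=float)
    n_doses = int(len(np.unique(dose)))
    if n_doses < 2:
        warnings.warn("single dose level: frequency is estimable but the "
                      "single-hit fit cannot be checked", stacklevel=2)

    total_cells = float((dose * tested).sum())
    if positive.sum() == 0:
        # P(all negative | f) = exp(-f * total_cells) = 0.05 at the bound
        f_upper = -np.log(0.05) / total_cells
        return FrequencyEstimate(
            frequency=0.0,
            one_in=np.inf,
            ci_one_in=(1.0 / f_upper, np.inf),
            log_likelihood=0.0,
            boundary=True,
            n_doses=n_doses,
        )
    if (positive == tested).all():
        # all positive: likelihood increases without bound in f
        def tail(logf):
            lam = np.exp(logf) * dose
            return np.log(-np.expm1(-lam)).dot(tested) - np.log(0.05)

        lo, hi = -30.0, 10.0
        f_lower = np.exp(optimize.brentq(tail, lo, hi))
        return FrequencyEstimate(
            frequency=np.inf,
            one_in=0.0,
            ci_one_in=(0.0, 1.0 / f_lower),
            log_likelihood=0.0,
            boundary=True,
            n_doses=n_doses,
        )

    # Newton iteration on beta = log f
    p0 = positive.sum() / tested.sum()
    beta = np.log(-np.log1p(-min(p0, 0.999)) / np.average(dose, weights=tested))
    for _ in range(100):
        score, info = _score_info(beta, dose, tested, positive)
        if info <= 0:
            break
        step = np.clip(score / info, -2.0, 2.0)
        beta += step
        if abs(step) < 1e-12:
            break
    score, info = _score_info(beta, dose, tested, positive)
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    f_hat = float(np.exp(beta))
    ll = _loglik(beta, dose, tested, positive)
    if profile_ci:
        target = ll - 0.5 * stats.chi2.ppf(0.95, 1)

        def prof(b):
            return _loglik(b, dose, tested, positive) - target

        b_lo = optimize.brentq(prof, beta - 20, beta)
        b_hi = optimize.brentq(prof, beta, beta + 20)
        ci = (1.0 / np.exp(b_hi), 1.0 / np.exp(b_lo))
    else:
        ci = (1.0 / np.exp(beta + _Z95 * se), 1.0 / np.exp(beta - _Z95 * se))
    return FrequencyEstimate(
        frequency=f_hat,
        one_in=1.0 / f_hat,
        ci_one_in=ci,
        log_likelihood=ll,
        boundary=False,
        n_doses=n_doses,
    )


def _group_max_loglik(sub: pd.DataFrame) -> float:
    """Supremum of the log-likelihood over f >= 0 for one group."""
    dose = sub["dose"].to_numpy(dtype=float)
    tested = sub["tested"].to_numpy(dtype=float)
    positive = sub["positive"].to_numpy(dtype=float)
    if positive.sum() == 0:
        return 0.0  # attained as f -> 0
    if (positive == tested).all():
        return 0.0  # attained as f -> inf
    est = fit_frequency(sub[["dose", "tested", "positive"]])
    return est.log_likelihood


def compare_frequencies(table: pd.DataFrame, group_col: str = "group") -> dict:
    """Likelihood-ratio test of equal frequencies across groups.

    Compares the pooled single-frequency model with per-group frequencies;
    the statistic is chi-square with (groups - 1) degrees of freedom.  When
    any group's MLE is on the boundary the comparison uses the supremum of
    its likelihood (profile over f >= 0) and warns.
    """
    _validate(table)
    groups = table[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    boundary = False
    ll_separate = 0.0
    fits = {}
    for g in groups:
        sub = table[table[group_col] == g]
        if sub["positive"].sum() == 0 or (sub["positive"] == sub["tested"]).all():
            boundary = True
            ll_separate += _group_max_loglik(sub)
            fits[g] = None
        else:
            est = fit_frequency(sub[["dose", "tested", "positive"]])
            ll_separate += est.log_likelihood
            fits[g] = est
    if boundary:
        warnings.warn("boundary MLE in at least one group; using profile "
                      "likelihood supremum for the comparison", stacklevel=2)
    pooled = fit_frequency(table[["dose", "tested", "positive"]])
    lrt = 2.0 * (ll_separate - pooled.log_likelihood)
    lrt = max(lrt, 0.0)
    df = len(groups) - 1
    p = float(stats.chi2.sf(lrt, df))
    return {
        "lrt": float(lrt),
        "df": df,
        "p": p,
        "pooled": pooled,
        "per_group": fits,
    }
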
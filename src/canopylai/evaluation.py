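"""Model validation statistics and the extinction-coefficient sensitivity.

Agreement between estimated and ground-truth LAI is summarised by the root
mean square error (RMSE), mean absolute error (MAE), mean bias error (MBE),
Willmott's index of agreement

    d = 1 − Σ(P_i − O_i)² / Σ(|P_i − Ō| + |O_i − Ō|)²

and the r² of an ordinary least-squares regression of predicted on
observed.  Each error is also expressed as a percentage of the mean
observed value.  A regression check tests the joint ideal of intercept 0
and slope 1 with two-sided t-tests.

Because the LAI equation is proportional to 1/k, a relative perturbation δ
of the extinction coefficient changes LAI by exactly 100·(1/(1+δ) − 1) %,
independent of the canopy: +30% on k gives −23.1% on LAI, −30% gives +42.9%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "EvalStats",
    "RegressionCheck",
    "SensitivityResult",
    "eval_stats",
    "regression_check",
    "k_sensitivity",
]


@dataclass(frozen=True)
class EvalStats:
    rmse: float
    mae: float
    mbe: float
    d: float
    r2: float
    n: int
    rmse_pct: float
    mae_pct: float
    mbe_pct: float


@dataclass(frozen=True)
class RegressionCheck:
    slope: float
    intercept: float
    r2: float
    p_intercept_eq_0: float
    p_slope_eq_1: float
    alpha: float
    intercept_ok: bool  # True when intercept = 0 is not rejected at alpha
    slope_ok: bool  # True when slope = 1 is not rejected at alpha


@dataclass(frozen=True)
class SensitivityResult:
    delta: float
    relative_lai_change: float  # percent


def eval_stats(observed, predicted) -> EvalStats:
    """Validation statistics comparing predicted against observed values."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    n = len(o)
    if n < 2:
        raise ValueError("at least 2 pairs are required")

    err = p - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mbe = float(np.mean(err))

    o_mean = float(o.mean())
    denom_d = float(np.sum((np.abs(p - o_mean) + np.abs(o - o_mean)) ** 2))
    d = 1.0 - float(np.sum(err**2)) / denom_d if denom_d > 0 else 1.0

    # r² of OLS of predicted on observed
    if np.ptp(o) == 0:
        r2 = float("nan")
    else:
        fit = sm.OLS(p, sm.add_constant(o)).fit()
        r2 = float(fit.rsquared)

    pct = (lambda s: s / o_mean * 100.0) if o_mean != 0 else (lambda s: float("nan"))
    return EvalStats(
        rmse=rmse, mae=mae, mbe=mbe, d=d, r2=r2, n=n,
        rmse_pct=pct(rmse), mae_pct=pct(mae), mbe_pct=pct(mbe),
    )


def regression_check(observed, predicted, alpha: float = 0.05) -> RegressionCheck:
    """OLS of predicted on observed with t-tests for intercept = 0 and
    slope = 1 (two-sided, n − 2 degrees of freedom)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    if len(o) < 3:
        raise ValueError("at least 3 pairs are required for the regression check")
    if np.ptp(o) == 0:
        raise ValueError("zero variance in observed values: regression undefined")

    fit = sm.OLS(p, sm.add_constant(o)).fit()
    intercept, slope = (float(b) for b in fit.params)
    p_int = float(fit.t_test([1.0, 0.0]).pvalue)  # H0: intercept = 0
    p_slope = float(fit.t_test(([0.0, 1.0], 1.0)).pvalue)  # H0: slope = 1
    return RegressionCheck(
        slope=slope,
        intercept=intercept,
        r2=float(fit.rsquared),
        p_intercept_eq_0=p_int,
        p_slope_eq_1=p_slope,
        alpha=alpha,
        intercept_ok=p_int >= alpha,
        slope_ok=p_slope >= alpha,
    )


def k_sensitivity(delta: float) -> SensitivityResult:
    """Relative LAI change caused by a relative perturbation of k.

    LAI ∝ 1/k, so scaling k by (1 + δ) scales LAI by 1/(1 + δ) for any
    canopy whatsoever; the result is the closed form 100·(1/(1+δ) − 1).
    """
    if delta <= -1.0:
        raise ValueError("delta must exceed -1 (k must remain positive)")
    return SensitivityResult(
        delta=delta, relative_lai_change=100.0 * (1.0 / (1.0 + delta) - 1.0)
    )
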
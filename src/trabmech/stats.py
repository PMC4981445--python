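"""Statistical layer: Pearson CIs, simple/stepwise OLS, Bland–Altman.

This mirrors the analysis plan of a small-n (~14 specimens) agreement study:
per-parameter Pearson correlations against the gold standard with Fisher-z
95% intervals, simple regressions predicting micro-FE outcomes from single
structure parameters (R² + two-tailed p), SPSS-style stepwise multiple
regression (probability-of-F entry 0.05 / removal 0.10) reporting the
single-predictor R² and the two-predictor adjusted R², and Bland–Altman
bias / limits of agreement for test–retest reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "StepwiseResult",
    "BlandAltmanResult",
    "pearson_ci",
    "simple_regression",
    "stepwise_regression",
    "adjusted_r2",
    "bland_altman",
    "descriptive_stats",
    "format_p",
]


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher-z confidence interval.

    Degenerate |r| = 1 collapses the interval onto r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:  # exact linear relation up to roundoff
        r = float(np.sign(r))
        return r, r, r
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(len(x) - 3)
    q = sps.norm.ppf(1 - alpha / 2)
    return r, float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


@dataclass
class RegressionResult:
    r2: float
    adjusted_r2: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n: int


def simple_regression(x, y, name: str = "x") -> RegressionResult:
    """OLS of y on one predictor: R² and the two-tailed slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(pd.DataFrame({name: x}))
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        coefficients=dict(fit.params),
        p_values=dict(fit.pvalues),
        n=len(x),
    )


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 - (1-R²)(n-1)/(n-k-1); may legitimately be negative."""
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class StepwiseResult:
    selected: list[str]
    r2_single: float | None
    adjusted_r2_two: float | None
    models: dict[int, RegressionResult] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.selected


def _ols(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(X)).fit()


def stepwise_regression(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the not-yet-entered candidate with the smallest partial
    p-value enters if p <= ``p_enter``; entered predictors with
    p >= ``p_remove`` are then removed (largest first).  Deterministic for a
    fixed table.  Reports the one-predictor R² and, when a second predictor
    enters, the two-predictor adjusted R².
    """
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least 1 candidate predictor")
    if len(y) < 4:
        raise ValueError("too few observations")
    selected: list[str] = []
    models: dict[int, RegressionResult] = {}
    while True:
        remaining = [c for c in X.columns if c not in selected]
        if not remaining:
            break
        pvals = {}
        for c in remaining:
            fit = _ols(y, X[selected + [c]])
            pvals[c] = float(fit.pvalues[c])
        best = min(pvals, key=lambda c: (pvals[c], list(X.columns).index(c)))
        if pvals[best] > p_enter:
            break
        selected.append(best)
        # backward sweep
        while len(selected) > 1:
            fit = _ols(y, X[selected])
            worst = max(selected, key=lambda c: float(fit.pvalues[c]))
            if float(fit.pvalues[worst]) >= p_remove:
                selected.remove(worst)
            else:
                break
        fit = _ols(y, X[selected])
        models[len(selected)] = RegressionResult(
            r2=float(fit.rsquared),
            adjusted_r2=float(fit.rsquared_adj),
            coefficients=dict(fit.params),
            p_values=dict(fit.pvalues),
            n=len(y),
        )
    return StepwiseResult(
        selected=selected,
        r2_single=models[1].r2 if 1 in models else None,
        adjusted_r2_two=models[2].adjusted_r2 if 2 in models else None,
        models=models,
    )


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    differences: np.ndarray
    systematic_error: bool  # True when 0 lies outside the CI of the bias


def bland_altman(a, b) -> BlandAltmanResult:
    """Paired-difference bias and 1.96·SD limits of agreement (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    if sd == 0:
        systematic = bias != 0.0
    else:
        ci_half = sps.t.ppf(0.975, len(d) - 1) * sd / np.sqrt(len(d))
        systematic = not (bias - ci_half <= 0.0 <= bias + ci_half)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        sd=sd,
        differences=d,
        systematic_error=bool(systematic),
    )


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean and sample SD (numeric columns only)."""
    num = table.select_dtypes("number")
    if len(num) < 2:
        raise ValueError("need n >= 2 rows")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def format_p(p: float, threshold: float = 0.001) -> str:
    """Report convention: below the threshold print 'p < 0.001'."""
    return f"p < {threshold}" if p < threshold else f"p = {p:.3f}"
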
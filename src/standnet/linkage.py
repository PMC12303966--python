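"""Regressions linking SQI to microbial community characteristics.

Four simple ordinary-least-squares regressions of the per-sample soil
quality index on: z-scored bacterial diversity, z-scored fungal diversity,
network complexity, and keystone-taxon relative abundance. Diversity
defaults to the Shannon index (Chao1 selectable); z-scores use the sample
SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD by default)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance; cannot z-score")
    return (v - v.mean()) / sd


@dataclass
class RegressionResult:
    """OLS fit of y on x with the quantities needed for a 95% band."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float
    residual_se: float
    x_mean: float
    sxx: float

    def confidence_band(self, x_grid, level: float = 0.95):
        """Mean-response confidence band over ``x_grid`` (for plotting)."""
        x = np.asarray(x_grid, dtype=float)
        t_crit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        se_mean = self.residual_se * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        yhat = self.intercept + self.slope * x
        return yhat - t_crit * se_mean, yhat + t_crit * se_mean


def simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
        slope_stderr=float(fit.stderr),
        residual_se=float(np.sqrt((resid**2).sum() / (len(x) - 2))),
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
    )


PREDICTORS = (
    "bacterial_diversity",
    "fungal_diversity",
    "network_complexity",
    "keystone_abundance",
)


def linkage_report(
    sqi: pd.Series,
    bacterial_diversity: pd.Series,
    fungal_diversity: pd.Series,
    complexity: pd.Series,
    keystone: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regress SQI on the four microbial predictors.

    Diversity predictors are z-scored; complexity and keystone abundance
    enter as computed. All inputs must cover the SQI sample ids; samples
    with a missing predictor value (e.g. a sub-network too small to
    summarize) are dropped pairwise. Returns one row per predictor with
    slope, R^2, p, n, and a significance flag at ``alpha``.
    """
    predictors = {
        "bacterial_diversity": bacterial_diversity,
        "fungal_diversity": fungal_diversity,
        "network_complexity": complexity,
        "keystone_abundance": keystone,
    }
    for name, series in predictors.items():
        missing = sqi.index.difference(series.index)
        if len(missing) > 0:
            raise ValueError(
                f"sample ids missing from {name}: {missing[:5].tolist()}"
            )
    rows = []
    for name, series in predictors.items():
        aligned = pd.concat(
            {"y": sqi, "x": series.reindex(sqi.index)}, axis=1
        ).dropna()
        x = aligned["x"].to_numpy()
        try:
            if name in ("bacterial_diversity", "fungal_diversity"):
                x = zscore(x)
            fit = simple_regression(x, aligned["y"].to_numpy())
        except ValueError:
            # degenerate predictor (e.g. no keystones detected): report NaN
            rows.append(
                {
                    "predictor": name,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "r_squared": np.nan,
                    "p_value": np.nan,
                    "n": len(aligned),
                    "significant": False,
                }
            )
            continue
        rows.append(
            {
                "predictor": name,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
                "significant": fit.p_value < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
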
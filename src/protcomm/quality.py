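"""Composite fruit production index and its diversity regressions.

The production index follows the multifunctionality-index recipe:
z-score every measured quality parameter across samples, then average
the z-scores within each sample. All parameters enter with positive
orientation by default; a per-parameter sign vector allows flipping
parameters where smaller is better (e.g. seed number, if desired).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import warn

#: The twelve fruit-quality parameters measured at harvest.
QUALITY_PARAMETERS = (
    "fruit_weight",
    "fruit_width",
    "fruit_height",
    "fruit_shape_index",
    "pericarp_thickness",
    "pericarp_weight",
    "valve_number",
    "valve_weight",
    "seed_number",
    "seed_weight",
    "solid_rate",
    "edible_rate",
)


@dataclass
class ProductionIndex:
    """Per-sample composite quality index with its audit trail.

    ``index`` is the arithmetic mean of each sample's parameter
    z-scores; ``zscores`` retains the full samples × parameters z-score
    table (each column has mean 0 and sample sd 1).
    """

    index: pd.Series
    zscores: pd.DataFrame


def production_index(
    quality: pd.DataFrame, signs: pd.Series | dict | None = None
) -> ProductionIndex:
    """Average of per-parameter z-scores (sample sd, n-1 denominator).

    Parameters with zero variance carry no ranking information and are
    excluded with a warning. ``signs`` maps parameter name to +1/-1 to
    flip negatively oriented parameters before averaging.
    """
    if quality.shape[0] < 2:
        raise ValueError("production_index needs at least 2 samples")
    if quality.shape[1] < 1:
        raise ValueError("production_index needs at least 1 parameter")
    sd = quality.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warn(f"zero-variance quality parameters excluded: {constant}")
    cols = [c for c in quality.columns if c not in constant]
    if not cols:
        z = pd.DataFrame(0.0, index=quality.index, columns=quality.columns)
        return ProductionIndex(index=z.mean(axis=1), zscores=z)
    z = (quality[cols] - quality[cols].mean(axis=0)) / sd[cols]
    if signs is not None:
        signs = pd.Series(signs)
        z = z * signs.reindex(cols).fillna(1.0)
    return ProductionIndex(index=z.mean(axis=1).rename("production_index"), zscores=z)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    R2: float
    p_value: float

    def __repr__(self) -> str:
        return (
            f"OLS: slope={self.slope:.4g} intercept={self.intercept:.4g} "
            f"R2={self.R2:.4f} p={self.p_value:.4g}"
        )


def index_regression(index: pd.Series, predictor: pd.Series) -> RegressionResult:
    """Ordinary least squares of the index on one predictor.

    The p-value is the two-sided t-test on the slope; R² equals the
    squared Pearson correlation of fitted and observed values.
    """
    df = pd.concat([index.rename("y"), predictor.rename("x")], axis=1).dropna()
    if df.shape[0] < 3:
        raise ValueError("index_regression needs at least 3 complete samples")
    if df["x"].std(ddof=0) == 0:
        raise ValueError("zero-variance predictor")
    fit = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    return RegressionResult(
        slope=float(fit.params["x"]),
        intercept=float(fit.params["const"]),
        R2=float(fit.rsquared),
        p_value=float(fit.pvalues["x"]),
    )
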
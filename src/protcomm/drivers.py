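"""Environmental drivers of community variation.

Two complementary views: redundancy analysis (RDA) — a constrained
ordination of the Hellinger-transformed community on standardized soil
variables, with a permutation test of the constrained variance — and a
random-forest ranking of soil variables by out-of-bag permutation
importance for a scalar community response (by default the first
principal coordinate of the Bray–Curtis matrix, the axis that
separates cultivation modes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

from .dataset import CommunityDataset


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of relative abundances."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    return np.sqrt(counts.div(totals, axis=0))


def _dependent_columns(x: np.ndarray, cols: list[str], tol: float = 1e-8) -> list[str]:
    """Columns linearly dependent on the columns before them."""
    dependent = []
    basis: list[np.ndarray] = []
    for j, name in enumerate(cols):
        candidate = np.column_stack(basis + [x[:, j]]) if basis else x[:, [j]]
        if np.linalg.matrix_rank(candidate, tol=tol) == len(basis):
            dependent.append(name)
        else:
            basis.append(x[:, j])
    return dependent


@dataclass
class RDAResults:
    """Fitted redundancy analysis.

    ``constrained_proportion`` is the fraction of total (centred,
    Hellinger-scale) community variance captured by the fitted values
    of the multivariate regression on the soil predictors.
    """

    constrained_proportion: float
    sample_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    eigenvalues: np.ndarray
    p_value: float
    n_perm: int

    def summary(self) -> str:
        return (
            f"RDA: constrained proportion={self.constrained_proportion:.4f} "
            f"p={self.p_value:.4g} ({self.n_perm} permutations)\n"
            f"axes: {len(self.eigenvalues)}"
        )


class RDA:
    """Redundancy analysis of a community on its soil variables.

    The response is the Hellinger-transformed relative-abundance table,
    the predictors are standardized soil variables; significance of the
    constrained proportion is assessed by permuting sample rows of the
    predictor matrix.
    """

    def __init__(self, dataset: CommunityDataset, soil_vars: list[str] | None = None):
        if dataset.soil is None:
            raise ValueError("RDA requires a dataset with a soil table")
        soil = dataset.soil.loc[dataset.sample_ids]
        if soil_vars is not None:
            soil = soil[list(soil_vars)]
        if soil.isna().any().any():
            bad = soil.columns[soil.isna().any()].tolist()
            raise ValueError(f"soil variables with missing values: {bad}")
        if soil.shape[1] < 2:
            raise ValueError("RDA needs at least 2 soil variables")
        if dataset.counts.shape[0] <= soil.shape[1]:
            raise ValueError("RDA needs more samples than predictors")
        sd = soil.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValueError(f"constant soil variables: {bad}")
        x = ((soil - soil.mean(axis=0)) / sd).to_numpy()
        dep = _dependent_columns(x, list(soil.columns))
        if dep:
            raise ValueError(f"collinear (rank-deficient) predictors: {dep}")
        self.dataset = dataset
        self.soil_columns = list(soil.columns)
        self._x = x
        y = hellinger(dataset.counts).to_numpy()
        self._y = y - y.mean(axis=0)

    @staticmethod
    def _constrained(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        total = (y**2).sum()
        return fitted, (fitted**2).sum() / total if total > 0 else 0.0

    def fit(self, n_perm: int = 999, seed: int | None = None) -> RDAResults:
        fitted, prop = self._constrained(self._x, self._y)
        rng = np.random.default_rng(seed)
        n = self._x.shape[0]
        exceed = 0
        for _ in range(n_perm):
            _, p = self._constrained(self._x[rng.permutation(n)], self._y)
            if p >= prop:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_perm)

        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        k = int((s > 1e-10 * max(1.0, s.max())) .sum())
        scores = u[:, :k] * s[:k]
        axes = [f"RDA{i + 1}" for i in range(k)]
        sample_scores = pd.DataFrame(scores, index=self.dataset.sample_ids, columns=axes)
        # biplot scores: correlation of each predictor with each axis
        biplot = np.zeros((self._x.shape[1], k))
        for j in range(self._x.shape[1]):
            for a in range(k):
                biplot[j, a] = np.corrcoef(self._x[:, j], scores[:, a])[0, 1]
        biplot_scores = pd.DataFrame(biplot, index=self.soil_columns, columns=axes)
        eig = (s[:k] ** 2) / (n - 1)
        return RDAResults(
            constrained_proportion=float(prop),
            sample_scores=sample_scores,
            biplot_scores=biplot_scores,
            eigenvalues=eig,
            p_value=float(p_value),
            n_perm=n_perm,
        )


def rda(
    dataset: CommunityDataset,
    soil_vars: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> RDAResults:
    """Convenience wrapper: ``RDA(dataset, soil_vars).fit(...)``."""
    return RDA(dataset, soil_vars).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Random-forest driver ranking
# ---------------------------------------------------------------------------


@dataclass
class DriverRanking:
    """Soil variables ranked by out-of-bag permutation importance.

    ``importances`` is sorted descending (mean OOB mean-squared-error
    increase when the variable is permuted, floored at 0);
    ``fit_score`` is the forest's out-of-bag R².
    """

    importances: pd.Series
    fit_score: float

    @property
    def top_driver(self) -> str:
        return str(self.importances.index[0])


def _bootstrap_indices(estimator, n_samples: int) -> np.ndarray:
    """Reproduce a forest member's bootstrap sample indices."""
    rng = check_random_state(estimator.random_state)
    return rng.randint(0, n_samples, n_samples)


def rf_drivers(
    soil_table: pd.DataFrame,
    response: pd.Series,
    seed: int | None = None,
    n_estimators: int = 500,
) -> DriverRanking:
    """Random-forest ranking of soil variables for a scalar response.

    A regression forest is fitted with bootstrap resampling; the fit is
    scored by out-of-bag R², and each variable's importance is the mean
    increase in out-of-bag mean squared error over trees when that
    variable's values are permuted among the tree's out-of-bag samples
    (the classic OOB permutation importance of regression forests).
    """
    x = soil_table.to_numpy(dtype=float)
    y = response.loc[soil_table.index].to_numpy(dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("rf_drivers needs at least 10 samples")
    if np.std(y) == 0:
        raise ValueError("constant response")
    forest = RandomForestRegressor(
        n_estimators=n_estimators, oob_score=True, bootstrap=True, random_state=seed
    )
    forest.fit(x, y)

    perm_rng = np.random.default_rng(seed)
    increases = np.zeros(p)
    n_used = np.zeros(p)
    for est in forest.estimators_:
        in_bag = np.bincount(_bootstrap_indices(est, n), minlength=n)
        oob = np.flatnonzero(in_bag == 0)
        if oob.size < 2:
            continue
        x_oob, y_oob = x[oob], y[oob]
        base = np.mean((y_oob - est.predict(x_oob)) ** 2)
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[perm_rng.permutation(oob.size), j]
            err = np.mean((y_oob - est.predict(x_perm)) ** 2)
            increases[j] += err - base
            n_used[j] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(n_used > 0, increases / np.maximum(n_used, 1), 0.0)
    imp = np.clip(imp, 0.0, None)
    ranking = pd.Series(imp, index=soil_table.columns, name="importance")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    return DriverRanking(importances=ranking, fit_score=float(forest.oob_score_))
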
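"""Random-forest permutation importance of protection drivers, with OOB tuning.

The response is the per-cell protected fraction and the predictors are the
nine preferential + opportunistic variables (biophysical gradients are
excluded: their importance would measure the *failure* of representativeness,
not a driver). The forest is a bagged ensemble of fully grown regression
trees (ntree=500, nodesize=1 by default) with mtry candidate predictors per
split; mtry is tuned by minimizing the out-of-bag MSE over all candidates
1..p.

Importance of a predictor: for every tree, the MSE on that tree's out-of-bag
cells is recorded before and after permuting the predictor's OOB values; the
per-tree differences are averaged over trees and normalized by their standard
deviation. Negative raw importances are clipped to zero and the result is
scaled to percentages summing to 100. Group averages pre-average animal and
plant richness into one biological-conservation value.

The ensemble is built from scikit-learn trees via ``BaggingRegressor`` (which
exposes the per-tree bootstrap samples the OOB statistic needs); the OOB
permutation statistic itself is computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigError, DegenerateDataError
from .variables import GROUP_ITEMS, RF_PREDICTORS

logger = logging.getLogger(__name__)

AUTO = "AUTO"
MIN_CELLS = 50   # below this the OOB error estimate is too unstable to tune on


@dataclass
class RFConfig:
    ntree: int = 500
    nodesize: int = 1
    mtry: int | str = AUTO
    mtry_candidates: tuple[int, ...] | None = None   # None -> 1..p
    seed: int = 0

    def validate(self, p: int) -> None:
        if self.ntree < 100:
            raise ConfigError("ntree must be >= 100")
        if self.nodesize < 1:
            raise ConfigError("nodesize must be >= 1")
        if self.mtry != AUTO and not (1 <= int(self.mtry) <= p):
            raise ConfigError(f"mtry must lie in 1..{p}")
        for m in self.mtry_candidates or ():
            if not (1 <= m <= p):
                raise ConfigError(f"mtry candidate {m} outside 1..{p}")


@dataclass
class ImportanceTable:
    variables: tuple[str, ...]
    raw_importance: dict[str, float]       # mean OOB-MSE increase / sd over trees
    percent_importance: dict[str, float]   # clipped, scaled to sum 100
    chosen_mtry: int
    oob_mse: float
    group_averages: dict[str, float]
    config: RFConfig = field(repr=False, default_factory=RFConfig)

    def to_frame(self) -> pd.DataFrame:
        from .variables import CANONICAL_VARIABLES
        return pd.DataFrame(
            {
                "variable": list(self.variables),
                "raw_importance": [self.raw_importance[v] for v in self.variables],
                "percent_importance": [self.percent_importance[v] for v in self.variables],
                "group": [CANONICAL_VARIABLES.get(v, "other") for v in self.variables],
            }
        )


# ---------------------------------------------------------------------------
# forest plumbing
# ---------------------------------------------------------------------------

def _fit_forest(X: np.ndarray, y: np.ndarray, mtry: int, config: RFConfig) -> BaggingRegressor:
    tree = DecisionTreeRegressor(max_features=mtry, min_samples_leaf=config.nodesize)
    forest = BaggingRegressor(
        estimator=tree,
        n_estimators=config.ntree,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _oob_masks(forest: BaggingRegressor, n: int):
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        mask = np.ones(n, dtype=bool)
        mask[samples] = False
        yield est, mask


def oob_mse(forest: BaggingRegressor, X: np.ndarray, y: np.ndarray) -> float:
    """Out-of-bag MSE: each cell predicted only by trees that never saw it."""
    n = len(y)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for est, mask in _oob_masks(forest, n):
        if mask.any():
            pred_sum[mask] += est.predict(X[mask])
            pred_cnt[mask] += 1
    used = pred_cnt > 0
    if not used.any():
        raise DegenerateDataError("no out-of-bag observations; increase ntree")
    resid = pred_sum[used] / pred_cnt[used] - y[used]
    return float(np.mean(resid ** 2))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def kendall_matrix(cells: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Pairwise tie-corrected Kendall tau-b among covariates over cells.

    Constant variables get NaN off-diagonal entries (association undefined).
    """
    variables = list(variables) if variables is not None else list(RF_PREDICTORS)
    if len(variables) < 2:
        raise DegenerateDataError("need at least 2 variables")
    if len(cells) < 10:
        raise DegenerateDataError("need at least 10 cells for Kendall's tau")
    data = {v: np.asarray(cells[v], dtype=float) for v in variables}
    constant = {v for v in variables if np.unique(data[v]).size < 2}
    tau = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            if a in constant or b in constant:
                t = np.nan
            else:
                t = stats.kendalltau(data[a], data[b]).statistic
            tau.loc[a, b] = tau.loc[b, a] = t
    return tau


def _design(cells: pd.DataFrame, response: str, predictors) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in [response, *predictors] if c not in cells.columns]
    if missing:
        raise ConfigError(f"columns missing from cell table: {missing}")
    X = np.asarray(cells[list(predictors)], dtype=float)
    y = np.asarray(cells[response], dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DegenerateDataError("non-finite values in forest input")
    return X, y


def tune_mtry(
    cells: pd.DataFrame,
    response: str = "protected_fraction",
    predictors=RF_PREDICTORS,
    config: RFConfig | None = None,
) -> int:
    """mtry minimizing the OOB-MSE over the candidate set; ties go low."""
    config = config or RFConfig()
    X, y = _design(cells, response, predictors)
    p = X.shape[1]
    config.validate(p)
    if len(y) < MIN_CELLS:
        raise DegenerateDataError(f"need >= {MIN_CELLS} cells to tune mtry, got {len(y)}")
    candidates = config.mtry_candidates or tuple(range(1, p + 1))
    scores = {}
    for m in candidates:
        forest = _fit_forest(X, y, m, config)
        scores[m] = oob_mse(forest, X, y)
        logger.debug("tune_mtry: mtry=%d OOB-MSE=%.6g", m, scores[m])
    best = min(sorted(scores), key=lambda m: scores[m])   # ties -> smaller mtry
    logger.info("tune_mtry: chose mtry=%d (OOB-MSE=%.6g)", best, scores[best])
    return int(best)


def permutation_importance(
    cells: pd.DataFrame,
    response: str = "protected_fraction",
    predictors=RF_PREDICTORS,
    config: RFConfig | None = None,
) -> ImportanceTable:
    """Percent-scaled OOB permutation importance of each predictor."""
    config = config or RFConfig()
    predictors = tuple(predictors)
    X, y = _design(cells, response, predictors)
    p = X.shape[1]
    config.validate(p)

    mtry = tune_mtry(cells, response, predictors, config) if config.mtry == AUTO \
        else int(config.mtry)
    forest = _fit_forest(X, y, mtry, config)
    final_oob = oob_mse(forest, X, y)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    n = len(y)
    diffs = np.empty((config.ntree, p))
    for t, (est, mask) in enumerate(_oob_masks(forest, n)):
        Xo, yo = X[mask], y[mask]
        base = np.mean((est.predict(Xo) - yo) ** 2)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            diffs[t, j] = np.mean((est.predict(Xp) - yo) ** 2) - base

    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    raw = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), mean)
    clipped = np.clip(raw, 0.0, None)
    if clipped.sum() <= 0:
        raise DegenerateDataError("no signal: all permutation importances <= 0")
    percent = 100.0 * clipped / clipped.sum()

    raw_map = dict(zip(predictors, map(float, raw)))
    percent_map = dict(zip(predictors, map(float, percent)))
    try:
        groups = group_averages(percent_map)
    except ConfigError:
        groups = {}   # non-canonical predictor set: no motivation groups defined
    return ImportanceTable(
        variables=predictors,
        raw_importance=raw_map,
        percent_importance=percent_map,
        chosen_mtry=mtry,
        oob_mse=final_oob,
        group_averages=groups,
        config=config,
    )


def group_averages(importances: dict[str, float], grouping=None) -> dict[str, float]:
    """Motivation-group means; tuple items (animal/plant richness) are
    pre-averaged into one biological-conservation value first."""
    grouping = grouping or GROUP_ITEMS
    out = {}
    for group, items in grouping.items():
        values = []
        for item in items:
            names = item if isinstance(item, tuple) else (item,)
            for name in names:
                if name not in importances:
                    raise ConfigError(f"unknown variable {name!r} in grouping")
            values.append(float(np.mean([importances[n] for n in names])))
        out[group] = float(np.mean(values))
    return out
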
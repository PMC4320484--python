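"""Pairwise lag-1 Granger causality screening.

For an ordered pair (x, y) the restricted model regresses y_t on an
intercept and its own lags, the unrestricted model adds the lags of x, and
the nested-model F statistic

    F = [(RSS0 - RSS1) / l] / [RSS1 / (T - l - (1 + 2l))]

is referred to F(l, T - 3l - 1). Both directions of every unordered pair
are screened and Benjamini-Hochberg adjusted as one family (degenerate
pairs excluded before correction).

Replicated time courses are collapsed to replicate means per timepoint and
standardized before testing. With very short series (the 6-point design this
pipeline targets) the lag-1 regression has few residual degrees of freedom;
the module warns rather than refuses, because such screens are still used —
carefully — in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidDesignError, ParameterError
from .univariate import adjust_bh

__all__ = ["GrangerParams", "GrangerPairResult", "prepare_series", "granger_pair", "granger_all_pairs"]


@dataclass(frozen=True)
class GrangerParams:
    lag: int = 1
    alpha: float = 0.05
    mode: str = "replicate-mean"

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ParameterError("lag must be >= 1")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.mode != "replicate-mean":
            raise ParameterError("only 'replicate-mean' series preparation is supported")


def prepare_series(
    values: pd.DataFrame, design: pd.DataFrame, mode: str = "replicate-mean"
) -> tuple[pd.DataFrame, list[str]]:
    """Average replicates per timepoint and standardize each series.

    Returns the feature x timepoint series matrix (time-ordered) and the
    list of constant series excluded as degenerate.
    """
    if mode != "replicate-mean":
        raise ParameterError("only 'replicate-mean' series preparation is supported")
    times = design.loc[values.columns, "time_h"]
    if times.nunique() < 2:
        raise InvalidDesignError("need at least 2 timepoints for a series")
    means = values.T.groupby(times.values).mean().T
    means = means[sorted(means.columns)]
    sd = means.std(axis=1, ddof=1)
    degenerate = means.index[(sd == 0) | sd.isna()].tolist()
    kept = means.drop(index=degenerate)
    standardized = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[kept.index], axis=0)
    return standardized, degenerate


class GrangerPairResult(NamedTuple):
    F: float
    p: float
    df1: int
    df2: int
    degenerate: bool


def _lag_matrix(z: np.ndarray, lag: int) -> np.ndarray:
    return np.column_stack([z[lag - k - 1 : len(z) - k - 1] for k in range(lag)])


def granger_pair(x, y, lag: int = 1) -> GrangerPairResult:
    """Does x improve the lag-``lag`` autoregressive prediction of y?"""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D series")
    T = len(y)
    if T < 2 * lag + 3:
        raise ParameterError(f"series length {T} < 2*lag+3 = {2 * lag + 3}")
    df1, df2 = lag, T - 3 * lag - 1
    if np.all(y == y[0]):
        return GrangerPairResult(0.0, 1.0, df1, df2, True)
    target = y[lag:]
    intercept = np.ones(T - lag)
    restricted = np.column_stack([intercept, _lag_matrix(y, lag)])
    unrestricted = np.column_stack([restricted, _lag_matrix(x, lag)])
    if np.linalg.matrix_rank(unrestricted) < unrestricted.shape[1]:
        return GrangerPairResult(0.0, 1.0, df1, df2, True)
    rss0 = _rss(restricted, target)
    rss1 = _rss(unrestricted, target)
    if rss1 <= 0:
        return GrangerPairResult(0.0, 1.0, df1, df2, True)
    f_stat = max(((rss0 - rss1) / df1) / (rss1 / df2), 0.0)
    p = float(stats.f.sf(f_stat, df1, df2))
    return GrangerPairResult(float(f_stat), p, df1, df2, False)


def _rss(design: np.ndarray, target: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid)


def granger_all_pairs(
    series: pd.DataFrame, params: GrangerParams = GrangerParams()
) -> pd.DataFrame:
    """Both directions of every pair, BH-adjusted as one family.

    ``series`` holds one row per feature, columns ordered in time. Constant
    series are excluded up front; singular pairs are flagged degenerate and
    excluded from the BH family, with p_adjusted = NaN.
    """
    T = series.shape[1]
    if T < 10:
        warnings.warn(
            f"series length {T} gives the lag-{params.lag} test very few residual "
            "degrees of freedom; treat results carefully"
        )
    arr = series.to_numpy(dtype=float)
    usable = [i for i in range(len(series)) if not np.all(arr[i] == arr[i, 0])]
    if len(usable) < 2:
        raise InvalidDesignError("need at least 2 non-degenerate series")
    rows = []
    for i, j in permutations(usable, 2):
        res = granger_pair(arr[i], arr[j], lag=params.lag)
        rows.append(
            (series.index[i], series.index[j], res.F, res.df1, res.df2, res.p, res.degenerate)
        )
    out = pd.DataFrame(
        rows, columns=["driver", "target", "F", "df1", "df2", "p_raw", "degenerate"]
    )
    out["p_adjusted"] = np.nan
    tested = ~out["degenerate"]
    if tested.any():
        out.loc[tested, "p_adjusted"] = adjust_bh(out.loc[tested, "p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] <= params.alpha
    return out
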
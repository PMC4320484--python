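"""Sequential K-nearest-neighbour imputation.

Features are split into complete and incomplete sets; incomplete features
are processed in order of ascending missing count (ties by input order).
Each is filled from the unweighted mean of its K nearest complete features
— Euclidean distance over the feature's observed sample positions, scaled
by sqrt(n_observed / n_used) so distances are comparable across missingness
patterns — and then joins the complete set, so early imputations can serve
as neighbours for later ones. Observed entries are never altered and the
procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UnimputableError

__all__ = ["ImputationParams", "ImputationResult", "impute_sknn"]


@dataclass(frozen=True)
class ImputationParams:
    """K: neighbour count; distance is Euclidean over co-observed samples."""

    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("K must be >= 1")


@dataclass
class ImputationResult:
    """Imputed matrix plus an audit trail of every filled cell."""

    data: pd.DataFrame
    audit: pd.DataFrame  # columns: feature, sample, value, neighbours


def impute_sknn(matrix: pd.DataFrame, params: ImputationParams = ImputationParams()) -> ImputationResult:
    """Fill every NaN by the sequential KNN scheme described above."""
    k = params.k
    values = matrix.to_numpy(dtype=float).copy()
    n_features, n_samples = values.shape
    observed = ~np.isnan(values)

    fully_missing = np.where(~observed.any(axis=1))[0]
    if len(fully_missing):
        names = matrix.index[fully_missing].tolist()
        raise UnimputableError(f"feature(s) with no observed values: {names[:5]}")
    too_sparse = np.where(observed.sum(axis=1) < 2)[0]
    if len(too_sparse):
        names = matrix.index[too_sparse].tolist()
        raise UnimputableError(f"feature(s) with fewer than 2 observed values: {names[:5]}")

    complete = [i for i in range(n_features) if observed[i].all()]
    incomplete = [i for i in range(n_features) if not observed[i].all()]
    if not incomplete:
        return ImputationResult(
            data=matrix.copy(),
            audit=pd.DataFrame(columns=["feature", "sample", "value", "neighbours"]),
        )
    if len(complete) < k:
        raise ParameterError(
            f"need at least K={k} complete features to start, found {len(complete)}"
        )

    # ascending missing count, ties by input order (stable sort)
    incomplete.sort(key=lambda i: (int((~observed[i]).sum()), i))

    audit_rows = []
    for i in incomplete:
        obs_cols = observed[i]
        n_obs = int(obs_cols.sum())
        pool = np.array(complete)
        diffs = values[pool][:, obs_cols] - values[i, obs_cols]
        # all candidates are complete, so n_used == n_obs and the
        # sqrt(n_obs / n_used) pattern correction is exactly 1
        dists = np.sqrt((diffs**2).sum(axis=1)) * np.sqrt(n_obs / n_obs)
        order = np.argsort(dists, kind="stable")[:k]
        neighbours = pool[order]
        fill_cols = np.where(~obs_cols)[0]
        fills = values[neighbours][:, fill_cols].mean(axis=0)
        values[i, fill_cols] = fills
        neighbour_names = "|".join(str(matrix.index[n]) for n in neighbours)
        for col, val in zip(fill_cols, fills):
            audit_rows.append(
                (matrix.index[i], matrix.columns[col], float(val), neighbour_names)
            )
        complete.append(i)

    data = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    audit = pd.DataFrame(audit_rows, columns=["feature", "sample", "value", "neighbours"])
    return ImputationResult(data=data, audit=audit)
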
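"""Functional-bin time profiling and biclustering.

Per-feature profiles are replicate means per timepoint expressed as a
percentage of the feature's maximum over the series, so every feature
attains 100 at its own peak. Profiles of differential features are grouped
by functional bin (mean +/- SD per timepoint), and feature-or-bin x
timepoint matrices are biclustered by agglomerative hierarchical clustering
on both axes with deterministic leaf ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import InvalidDesignError, ParameterError

__all__ = [
    "percent_of_max",
    "BinProfiles",
    "bin_aggregate",
    "BiclusterResult",
    "bicluster_heatmap",
    "linkage_to_newick",
]


def percent_of_max(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per timepoint, scaled to percent of the series maximum.

    Features whose maximum replicate-mean is not positive cannot be scaled;
    they are dropped with a warning.
    """
    times = design.loc[values.columns, "time_h"]
    means = values.T.groupby(times.values).mean().T
    means = means[sorted(means.columns)]
    maxima = means.max(axis=1)
    bad = maxima.index[~(maxima > 0)].tolist()
    if bad:
        warnings.warn(f"dropping {len(bad)} feature(s) without a positive maximum: {bad[:5]}")
        means = means.drop(index=bad)
        maxima = maxima.drop(index=bad)
    return means.div(maxima, axis=0) * 100.0


@dataclass
class BinProfiles:
    """Per-bin mean and SD percent-of-max profiles."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    n_members: pd.Series
    small_bins: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)


def bin_aggregate(
    profiles: pd.DataFrame,
    binmap: Mapping[str, str] | pd.Series,
    significant: Iterable[str] | None = None,
) -> BinProfiles:
    """Group differential features' profiles by functional bin.

    ``significant`` restricts to features passing the univariate threshold
    (None = keep all). Features without a bin assignment are reported as
    unmapped; bins with fewer than 2 members are flagged.
    """
    binmap = pd.Series(dict(binmap)) if not isinstance(binmap, pd.Series) else binmap
    if binmap.empty:
        raise ParameterError("bin map is empty")
    keep = profiles.index if significant is None else [f for f in profiles.index if f in set(significant)]
    sub = profiles.loc[keep]
    unmapped = [f for f in sub.index if f not in binmap.index]
    mapped = sub.loc[[f for f in sub.index if f in binmap.index]]
    if mapped.empty:
        warnings.warn("no differential features carry a bin assignment")
        empty = pd.DataFrame(columns=profiles.columns)
        return BinProfiles(empty, empty.copy(), pd.Series(dtype=int), [], unmapped)
    bins = binmap.loc[mapped.index]
    grouped = mapped.groupby(bins.values)
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.size()
    small = n.index[n < 2].tolist()
    return BinProfiles(mean=mean, sd=sd, n_members=n, small_bins=small, unmapped=unmapped)


@dataclass
class BiclusterResult:
    """Row/column-ordered matrix with the linkages behind the ordering."""

    matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str


def bicluster_heatmap(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> BiclusterResult:
    """Agglomerative clustering of rows and columns with deterministic leaves."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ParameterError("need at least 2 rows and 2 columns to bicluster")
    if matrix.isna().any().any():
        raise ParameterError("NaN in input; impute before clustering")
    row_link = hierarchy.linkage(pdist(matrix.to_numpy(dtype=float), metric=metric), method=method)
    col_link = hierarchy.linkage(pdist(matrix.to_numpy(dtype=float).T, metric=metric), method=method)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    ordered = matrix.loc[row_order, col_order]
    return BiclusterResult(
        matrix=ordered,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[str(r) for r in row_order],
        col_order=[str(c) for c in col_order],
        row_newick=linkage_to_newick(row_link, [str(i) for i in matrix.index]),
        col_newick=linkage_to_newick(col_link, [str(c) for c in matrix.columns]),
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def clean(label: str) -> str:
        return label.replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_").replace(":", "_").replace(";", "_")

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{clean(labels[node.id])}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"
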
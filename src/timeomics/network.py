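"""Relevance networks from sPLS models and pairwise correlations.

The sPLS similarity between predictor i and response j is the standard
relevance-network construction for regression-mode sparse PLS:

    sim(i, j) = sum_h cor(x_i, t_h) * cor(y_j, t_h)

over the fitted components' X-scores t_h. Thresholding |association| at a
cutoff yields an undirected, typed, signed network; edges below the cutoff
are absent, not zero-weighted.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, StateError
from .latent import LatentModel

__all__ = [
    "spls_similarity",
    "pairwise_correlation",
    "threshold_network",
    "merge_networks",
    "write_graphml",
    "write_edge_list",
]


def _column_correlations(data: pd.DataFrame, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each data column with each score column."""
    arr = data.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0, keepdims=True)
    sd = arr.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) get zero similarity"
        )
    sd[constant] = 1.0
    z = arr / sd
    s = scores - scores.mean(axis=0, keepdims=True)
    s_sd = s.std(axis=0, ddof=0)
    s_sd[s_sd == 0] = 1.0
    s = s / s_sd
    cors = z.T @ s / len(data)
    cors[constant, :] = 0.0
    return cors


def spls_similarity(model: LatentModel, X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Bipartite predictor x response association matrix from a fitted model.

    Values are clipped to [-1, 1]; clip events are logged as warnings.
    """
    if model.x_scores is None or model.x_scores.empty:
        raise StateError("sPLS model has no fitted scores")
    scores = model.x_scores.to_numpy(dtype=float)
    cx = _column_correlations(X, scores)
    cy = _column_correlations(Y, scores)
    sim = cx @ cy.T
    n_clip = int((np.abs(sim) > 1).sum())
    if n_clip:
        warnings.warn(f"clipped {n_clip} similarity value(s) to [-1, 1]")
        sim = np.clip(sim, -1.0, 1.0)
    return pd.DataFrame(sim, index=X.columns, columns=Y.columns)


def pairwise_correlation(values: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Feature x feature correlation matrix (features in rows, samples in columns).

    Constant features yield undefined associations, recorded as NaN (no edge)
    with a warning.
    """
    if values.shape[1] < 3:
        raise ParameterError("need at least 3 samples for pairwise correlation")
    if method not in ("pearson", "spearman"):
        raise ParameterError("method must be 'pearson' or 'spearman'")
    constant = values.std(axis=1, ddof=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) have undefined correlations"
        )
    arr = values.to_numpy(dtype=float)
    if method == "spearman":
        arr = np.apply_along_axis(stats.rankdata, 1, arr)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    corr = pd.DataFrame(corr, index=values.index, columns=values.index)
    valid = ~constant
    diag = pd.Series(np.where(valid, 1.0, np.nan), index=values.index)
    np.fill_diagonal(corr.values, diag)
    return corr


def threshold_network(
    assoc: pd.DataFrame,
    cutoff: float,
    node_blocks: Mapping[str, str] | None = None,
    provenance: str = "pairwise-correlation",
    keep_isolated: bool = False,
) -> nx.Graph:
    """Edges where |association| >= cutoff; isolated nodes dropped by default."""
    if not (0 < cutoff <= 1):
        raise ParameterError("cutoff must lie in (0, 1]")
    graph = nx.Graph(cutoff=cutoff)
    symmetric = assoc.index.equals(assoc.columns)
    if keep_isolated:
        for name in set(assoc.index) | set(assoc.columns):
            graph.add_node(name)
    rows = list(assoc.index)
    cols = list(assoc.columns)
    arr = assoc.to_numpy(dtype=float)
    for i, source in enumerate(rows):
        j_start = i + 1 if symmetric else 0
        for j in range(j_start, len(cols)):
            target = cols[j]
            if source == target:
                continue
            w = arr[i, j]
            if np.isnan(w) or abs(w) < cutoff:
                continue
            graph.add_edge(
                source,
                target,
                weight=float(w),
                sign=1 if w >= 0 else -1,
                provenance=provenance,
            )
    if node_blocks is not None:
        for node in graph.nodes:
            graph.nodes[node]["block"] = node_blocks.get(node, "unknown")
    return graph


def merge_networks(*graphs: nx.Graph) -> nx.Graph:
    """Union of edge sets, keeping each edge's provenance (first wins on clash)."""
    merged = nx.Graph()
    for g in graphs:
        for node, attrs in g.nodes(data=True):
            if node not in merged:
                merged.add_node(node, **attrs)
        for u, v, attrs in g.edges(data=True):
            if not merged.has_edge(u, v):
                merged.add_edge(u, v, **attrs)
    return merged


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path: str | Path, directed: bool = False) -> None:
    """SIF-style TSV: source, target, weight, sign, provenance (sorted, deterministic)."""
    rows = [
        (u, v, d.get("weight", np.nan), d.get("sign", 0), d.get("provenance", ""))
        for u, v, d in graph.edges(data=True)
    ]
    rows.sort()
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "provenance"])
    if directed:
        df["directed"] = True
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
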
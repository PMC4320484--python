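"""Autoscaling, PCA, PLS-DA and sparse PLS in regression mode.

The sparse PLS core follows the classical alternating power scheme: per
component h it iterates

    u  <-  select_keepX(X_h' Y_h v),  normalized to ||u|| = 1
    v  <-  Y_h' X_h u,                normalized to ||v|| = 1

where ``select_keepX`` keeps the keepX largest-|.| entries of the weight
vector (ties broken by feature order) and zeroes the rest. Scores are
t_h = X_h u; both X and Y are deflated with t_h (regression mode), which
makes successive X-scores orthogonal. PLS-DA is the same core run against a
one-hot class matrix with no sparsity, and PCA is a plain SVD — all with a
deterministic sign convention (the largest-|weight| entry of each component
is positive) so fitted models are reproducible bit for bit.

Scaling uses the n-1 denominator for the SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, ParameterError, StateError

__all__ = ["ScalingParams", "LatentModel", "autoscale", "pca", "plsda", "spls"]


@dataclass
class ScalingParams:
    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)


def autoscale(X: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Center each feature (column) to mean 0 and scale to SD 1 (ddof=1).

    Constant features cannot be scaled; they are dropped with a warning.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): {constant[:5]}")
    keep = [c for c in X.columns if c not in set(constant)]
    scaled = (X[keep] - mean[keep]) / sd[keep]
    return scaled, ScalingParams(mean=mean[keep], sd=sd[keep], dropped=constant)


def unscale(X: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    return X * params.sd + params.mean


@dataclass
class LatentModel:
    """Scores, loading weights and bookkeeping for PCA / PLS-DA / sPLS."""

    method: str
    ncomp: int
    x_scores: pd.DataFrame
    x_weights: pd.DataFrame
    y_scores: pd.DataFrame | None = None
    y_weights: pd.DataFrame | None = None
    keepX: list[int] | None = None
    explained_variance: np.ndarray | None = None
    iterations: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    classes: list | None = None

    def selected(self, comp: int | None = None) -> list[str]:
        """Features with nonzero X-weight on component ``comp`` (or any)."""
        w = self.x_weights
        if comp is not None:
            mask = w.iloc[:, comp] != 0
        else:
            mask = (w != 0).any(axis=1)
        return w.index[mask].tolist()

    def summary(self) -> dict:
        return {
            "method": self.method,
            "ncomp": self.ncomp,
            "keepX": self.keepX,
            "iterations": self.iterations,
            "converged": self.converged,
            "explained_variance": None
            if self.explained_variance is None
            else [float(v) for v in self.explained_variance],
        }


def _component_names(n: int) -> list[str]:
    return [f"comp{i + 1}" for i in range(n)]


def _fix_sign(u: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Make the largest-|u| entry positive; flip companions consistently."""
    j = int(np.argmax(np.abs(u)))
    if u[j] < 0:
        return (-u,) + tuple(-o for o in others)
    return (u,) + others


def pca(X: pd.DataFrame, ncomp: int) -> LatentModel:
    """SVD-based principal components of an autoscaled matrix (samples x features)."""
    n, p = X.shape
    if ncomp > min(n - 1, p):
        raise ParameterError(f"ncomp={ncomp} exceeds min(n-1, p)={min(n - 1, p)}")
    arr = X.to_numpy(dtype=float)
    u_mat, s, vt = np.linalg.svd(arr, full_matrices=False)
    total = float((s**2).sum())
    scores = np.empty((n, ncomp))
    loadings = np.empty((p, ncomp))
    for h in range(ncomp):
        load, score = _fix_sign(vt[h], u_mat[:, h] * s[h])
        loadings[:, h], scores[:, h] = load, score
    names = _component_names(ncomp)
    return LatentModel(
        method="pca",
        ncomp=ncomp,
        x_scores=pd.DataFrame(scores, index=X.index, columns=names),
        x_weights=pd.DataFrame(loadings, index=X.columns, columns=names),
        explained_variance=(s[:ncomp] ** 2) / total,
    )


def _select_keepX(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|w| entries (ties by feature order), zero the rest."""
    if keep >= w.size:
        return w
    order = np.lexsort((np.arange(w.size), -np.abs(w)))  # stable: |w| desc, index asc
    out = np.zeros_like(w)
    idx = order[:keep]
    out[idx] = w[idx]
    return out


def spls(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    ncomp: int = 3,
    keepX: int | list[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LatentModel:
    """Sparse PLS (regression mode): X (n x p) predicts Y (n x q).

    Both matrices are expected autoscaled. ``keepX`` is the number of
    predictor variables retained per component (None = all). A component
    that fails to converge within ``max_iter`` is flagged, not fatal.
    """
    if len(X) != len(Y):
        raise ParameterError("X and Y must have the same number of samples")
    n, p = X.shape
    q = Y.shape[1]
    if ncomp < 1 or ncomp > min(n - 1, p):
        raise ParameterError(f"ncomp={ncomp} out of range for X of shape {X.shape}")
    if keepX is None:
        keep_list = [p] * ncomp
    elif isinstance(keepX, int):
        keep_list = [keepX] * ncomp
    else:
        keep_list = list(keepX)
        if len(keep_list) != ncomp:
            raise ParameterError("keepX list must have one entry per component")
    if any(k < 1 or k > p for k in keep_list):
        raise ParameterError("keepX entries must lie in [1, p]")

    Xh = X.to_numpy(dtype=float).copy()
    Yh = Y.to_numpy(dtype=float).copy()
    total_x = float((Xh**2).sum())
    u_all = np.zeros((p, ncomp))
    v_all = np.zeros((q, ncomp))
    t_all = np.zeros((n, ncomp))
    s_all = np.zeros((n, ncomp))
    ev = np.zeros(ncomp)
    iterations, converged = [], []

    for h in range(ncomp):
        M = Xh.T @ Yh  # p x q cross-covariance of the deflated matrices
        # initialize v from the leading right singular vector of M
        if q == 1:
            v = np.ones(1)
        else:
            _, _, vt = np.linalg.svd(M, full_matrices=False)
            v = vt[0]
            v /= np.linalg.norm(v) or 1.0
        u = np.zeros(p)
        n_iter, ok = 0, False
        for n_iter in range(1, max_iter + 1):
            u_new = _select_keepX(M @ v, keep_list[h])
            norm_u = np.linalg.norm(u_new)
            if norm_u == 0:
                break
            u_new /= norm_u
            v_new = M.T @ u_new
            norm_v = np.linalg.norm(v_new)
            if norm_v > 0:
                v_new /= norm_v
            if max(np.abs(u_new - u).max(), np.abs(v_new - v).max()) < tol:
                u, v = u_new, v_new
                ok = True
                break
            u, v = u_new, v_new
        u, v = _fix_sign(u, v)
        t = Xh @ u
        tt = float(t @ t)
        if tt > 0:
            x_load = Xh.T @ t / tt
            y_load = Yh.T @ t / tt
            before = float((Xh**2).sum())
            Xh = Xh - np.outer(t, x_load)
            Yh = Yh - np.outer(t, y_load)
            ev[h] = (before - float((Xh**2).sum())) / total_x if total_x > 0 else 0.0
        u_all[:, h], v_all[:, h], t_all[:, h] = u, v, t
        s_all[:, h] = Y.to_numpy(dtype=float) @ v
        iterations.append(n_iter)
        converged.append(ok)

    names = _component_names(ncomp)
    return LatentModel(
        method="spls",
        ncomp=ncomp,
        x_scores=pd.DataFrame(t_all, index=X.index, columns=names),
        x_weights=pd.DataFrame(u_all, index=X.columns, columns=names),
        y_scores=pd.DataFrame(s_all, index=Y.index, columns=names),
        y_weights=pd.DataFrame(v_all, index=Y.columns, columns=names),
        keepX=keep_list,
        explained_variance=ev,
        iterations=iterations,
        converged=converged,
    )


def plsda(X: pd.DataFrame, labels, ncomp: int = 2) -> LatentModel:
    """PLS discriminant analysis: the sPLS core against one-hot classes.

    ``labels`` gives one class per sample (aligned with X rows). No sparsity
    is applied (keepX = p).
    """
    labels = pd.Series(list(labels), index=X.index)
    classes = sorted(labels.unique(), key=str)
    if len(classes) < 2:
        raise InvalidDesignError("PLS-DA needs at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        warnings.warn(
            f"class(es) with a single sample: {counts.index[counts < 2].tolist()} "
            "(low degrees of freedom)"
        )
    dummy = pd.DataFrame(
        {c: (labels == c).astype(float) for c in classes}, index=X.index
    )
    dummy_scaled, _ = autoscale(dummy)
    model = spls(X, dummy_scaled, ncomp=ncomp, keepX=None)
    model.method = "plsda"
    model.classes = classes
    return model


def model_from_state(model: LatentModel) -> LatentModel:
    if model.x_scores is None or model.x_scores.empty:
        raise StateError("model has no fitted scores")
    return model
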
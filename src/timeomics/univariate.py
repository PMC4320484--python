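"""Per-feature significance testing.

Two paths mirror how time-course omics blocks are usually treated:
spectral-count-derived protein abundances go through a nonparametric
Kruskal-Wallis test on log-transformed values, while metabolite and
physiology variables go through one-way ANOVA followed by Tukey HSD with a
compact letter display. Benjamini-Hochberg adjustment is applied across
features within a block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidDesignError, ParameterError

__all__ = [
    "pseudocount",
    "log_transform",
    "kruskal_wallis",
    "anova_tukey",
    "adjust_bh",
    "compact_letters",
]


def pseudocount(matrix: pd.DataFrame) -> float:
    """Half the smallest positive value, or 0 if the matrix has no zeros."""
    arr = matrix.to_numpy(dtype=float)
    if not (arr == 0).any():
        return 0.0
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ParameterError("matrix has no positive values to derive a pseudocount from")
    return float(positive.min()) / 2.0


def log_transform(matrix: pd.DataFrame, c: float | None = None) -> pd.DataFrame:
    """log2(x + c); by default c is the half-minimum pseudocount."""
    arr = matrix.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ParameterError("log transform requires nonnegative values")
    if c is None:
        c = pseudocount(matrix)
    return np.log2(matrix + c)


def _grouped(matrix: pd.DataFrame, groups: pd.Series):
    """Yield per-feature lists of per-group arrays; validates the design."""
    groups = groups.loc[matrix.columns]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise InvalidDesignError("need at least 2 groups")
    cols = {g: [s for s in matrix.columns if groups[s] == g] for g in levels}
    small = [g for g, c in cols.items() if len(c) < 2]
    if small:
        raise InvalidDesignError(f"group(s) with fewer than 2 observations: {small}")
    return levels, cols


def kruskal_wallis(matrix: pd.DataFrame, groups: pd.Series, adjust: bool = True) -> pd.DataFrame:
    """Kruskal-Wallis H (tie-corrected) per feature; chi-square p on g-1 df.

    Features whose values are all identical are flagged degenerate with
    p = 1. ``groups`` maps sample -> group label (e.g. the timepoint).
    """
    levels, cols = _grouped(matrix, groups)
    rows = []
    for feature in matrix.index:
        arrays = [matrix.loc[feature, cols[g]].to_numpy(dtype=float) for g in levels]
        flat = np.concatenate(arrays)
        if np.all(flat == flat[0]):
            rows.append((feature, 0.0, len(levels) - 1, 1.0, True))
            continue
        h, p = stats.kruskal(*arrays)
        rows.append((feature, float(h), len(levels) - 1, float(p), False))
    out = pd.DataFrame(
        rows, columns=["feature", "statistic", "df", "p_raw", "degenerate"]
    ).set_index("feature")
    if adjust:
        out["p_adjusted"] = adjust_bh(out["p_raw"].to_numpy())
    return out


_Q_CRIT_CACHE: dict[tuple[float, int, int], float] = {}


def _tukey_critical(alpha: float, k: int, df: int) -> float:
    """Cached studentized-range critical value q_{1-alpha; k, df}."""
    key = (alpha, k, df)
    if key not in _Q_CRIT_CACHE:
        _Q_CRIT_CACHE[key] = float(stats.studentized_range.ppf(1 - alpha, k, df))
    return _Q_CRIT_CACHE[key]


def anova_tukey(
    matrix: pd.DataFrame, groups: pd.Series, alpha: float = 0.05, adjust: bool = True
) -> pd.DataFrame:
    """One-way ANOVA F plus all pairwise Tukey HSD comparisons per feature.

    Returns, per feature, the F statistic, its df pair, raw/BH-adjusted
    p-values and a compact letter display (one letter group per group level
    in sorted order, comma-joined): groups share a letter iff their Tukey
    p >= alpha. Pairwise significance is decided by comparing the
    Tukey-Kramer studentized range statistic

        q_ij = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))

    against the cached critical value q_{1-alpha; k, df}, which is exactly
    equivalent to thresholding the Tukey p-value at alpha (exact pairwise
    p-values for a single feature are available via ``tukey_pairwise_p``).
    Features with zero within-group variance are flagged degenerate with a
    single letter.
    """
    levels, cols = _grouped(matrix, groups)
    k = len(levels)
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ParameterError("NaN in input; impute before testing")
    col_pos = {s: i for i, s in enumerate(matrix.columns)}
    idx = [np.array([col_pos[s] for s in cols[lv]]) for lv in levels]
    n_g = np.array([len(i) for i in idx])
    n_total = int(n_g.sum())
    df1, df2 = k - 1, n_total - k

    means = np.column_stack([arr[:, i].mean(axis=1) for i in idx])  # features x k
    grand = arr.mean(axis=1)
    ssb = (n_g * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(len(arr))
    for g_i, i in enumerate(idx):
        ssw += ((arr[:, i] - means[:, g_i][:, None]) ** 2).sum(axis=1)
    degenerate = ssw == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / df1) / (ssw / df2)
    p_raw = np.where(degenerate, 1.0, stats.f.sf(np.where(degenerate, np.nan, f_stat), df1, df2))
    f_stat = np.where(degenerate, np.nan, f_stat)

    q_crit = _tukey_critical(alpha, k, df2)
    mse = np.where(degenerate, np.nan, ssw / df2)
    letters_out = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    se = np.sqrt(np.outer(1.0 / n_g, np.ones(k)) + np.outer(np.ones(k), 1.0 / n_g))
    for f in range(len(arr)):
        if degenerate[f]:
            letters_out.append(",".join(["a"] * k))
            continue
        sig = np.zeros((k, k), dtype=bool)
        scale = np.sqrt(mse[f] / 2.0)
        for i, j in pairs:
            q = abs(means[f, i] - means[f, j]) / (scale * se[i, j])
            sig[i, j] = sig[j, i] = q > q_crit
        letters_out.append(",".join(compact_letters_from_significance(sig)))

    out = pd.DataFrame(
        {
            "statistic": f_stat,
            "df1": df1,
            "df2": df2,
            "p_raw": p_raw,
            "letters": letters_out,
            "degenerate": degenerate,
        },
        index=matrix.index.rename("feature"),
    )
    if adjust:
        out["p_adjusted"] = adjust_bh(out["p_raw"].to_numpy())
    return out


def tukey_pairwise_p(arrays: list[np.ndarray]) -> np.ndarray:
    """Exact Tukey-Kramer pairwise p-values for one feature's group arrays.

    Intended for fixture-scale use (the studentized-range survival function
    is numerically expensive); ``anova_tukey`` itself only needs pairwise
    significance and uses the cached critical value instead.
    """
    k = len(arrays)
    n_g = np.array([len(a) for a in arrays])
    df2 = int(n_g.sum()) - k
    means = np.array([a.mean() for a in arrays])
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = ssw / df2
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / n_g[i] + 1.0 / n_g[j]))
            q = abs(means[i] - means[j]) / se
            p[i, j] = p[j, i] = float(stats.studentized_range.sf(q, k, df2))
    return p


def compact_letters(pairwise_p: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Compact letter display from a symmetric matrix of pairwise p-values.

    Two groups share a letter iff they are *not* significantly different at
    ``alpha``.
    """
    return compact_letters_from_significance(np.asarray(pairwise_p) < alpha)


def compact_letters_from_significance(significant: np.ndarray) -> list[str]:
    """Compact letter display by insert-and-absorb.

    ``significant[i, j]`` is True when groups i and j differ significantly;
    the returned letter strings share a letter exactly for the other pairs.
    """
    g = significant.shape[0]
    columns: list[set[int]] = [set(range(g))]
    for i in range(g):
        for j in range(i + 1, g):
            if significant[i, j]:
                for col in [c for c in columns if i in c and j in c]:
                    columns.remove(col)
                    columns.extend([col - {i}, col - {j}])
                # absorb: drop columns contained in another column
                columns = [
                    c
                    for idx, c in enumerate(columns)
                    if c
                    and not any(
                        c < other or (c == other and idx2 < idx)
                        for idx2, other in enumerate(columns)
                        if idx2 != idx
                    )
                ]
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(g)]
    for pos, col in enumerate(columns):
        mark = alphabet[pos % len(alphabet)] * (pos // len(alphabet) + 1)
        for i in sorted(col):
            letters[i] += mark
    return letters


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
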
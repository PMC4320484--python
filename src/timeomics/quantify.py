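"""Quantitation and presence filtering.

Proteins are quantified by the normalized spectral abundance factor,

    NSAF_k = (PSM_k / L_k) / sum_i (PSM_i / L_i)     (per sample),

metabolite peak areas are sample-centrically normalized (divided by the
total area of their sample), and physiological variables are optionally
expressed relative to their mean at the first sampling time. Presence
filters reproduce the printed quantitation rules: a protein must be seen in
all replicates of at least one timepoint or in five samples from distinct
timepoints; a metabolite must be seen in a full replicate set or in more
than 18 samples overall.

Detection means a strictly positive stored value; NaN entries are "missing,
to impute" and never count as detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, SpectralCountTable, check_same_samples
from .errors import (
    DegenerateBaselineError,
    DegenerateSampleError,
    ParameterError,
    SchemaError,
)

__all__ = [
    "FilterParams",
    "compute_nsaf",
    "filter_min_abundance",
    "filter_replicate_presence",
    "normalize_metabolites",
    "filter_metabolite_presence",
    "normalize_physio_t0",
    "merge_blocks",
    "presence_report",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the printed quantitation filters.

    tau: minimum (max-over-samples) NSAF abundance.
    n_required: replicates required at one timepoint (None = all replicates
        present in the design at that timepoint).
    alt_times: fallback clause — detections at this many distinct timepoints
        (or, with alt_mode="any_samples", in this many samples anywhere).
    metabolite_min_samples: metabolite fallback — strictly more detections
        than this, at any timepoints.
    abundance_mode: whether tau applies to the per-protein "max" or "mean"
        NSAF across samples.
    """

    tau: float = 0.001
    n_required: int | None = None
    alt_times: int = 5
    metabolite_min_samples: int = 18
    abundance_mode: str = "max"
    alt_mode: str = "distinct_times"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ParameterError("tau must be > 0")
        if self.abundance_mode not in ("max", "mean"):
            raise ParameterError("abundance_mode must be 'max' or 'mean'")
        if self.alt_mode not in ("distinct_times", "any_samples"):
            raise ParameterError("alt_mode must be 'distinct_times' or 'any_samples'")


def compute_nsaf(table: SpectralCountTable) -> pd.DataFrame:
    """Length-normalized relative abundance; each sample column sums to 1."""
    saf = table.counts.div(table.lengths, axis=0)
    totals = saf.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"sample(s) with all-zero spectral counts: {list(dead.index)}"
        )
    return saf.div(totals, axis=1)


def filter_min_abundance(nsaf: pd.DataFrame, tau: float = 0.001, mode: str = "max") -> pd.DataFrame:
    """Retain proteins whose max- (or mean-) over-samples NSAF is >= tau."""
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    summary = nsaf.max(axis=1) if mode == "max" else nsaf.mean(axis=1)
    return nsaf.loc[summary >= tau]


def _check_design(matrix: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = set(matrix.columns) - set(design.index)
    if missing:
        raise SchemaError(f"samples absent from design: {sorted(missing)}")


def presence_report(
    matrix: pd.DataFrame, design: pd.DataFrame, params: FilterParams, metabolite: bool = False
) -> pd.DataFrame:
    """Per-feature filter report: which clause (if any) each feature satisfies."""
    _check_design(matrix, design)
    detected = matrix.gt(0) & matrix.notna()
    times = design.loc[matrix.columns, "time_h"]
    full_set = pd.Series(False, index=matrix.index)
    for t, cols in matrix.columns.to_series().groupby(times.values):
        group = detected[list(cols)]
        need = params.n_required if params.n_required is not None else group.shape[1]
        full_set |= group.sum(axis=1) >= need
    if metabolite:
        fallback = detected.sum(axis=1) > params.metabolite_min_samples
        fallback_name = "clause_many_samples"
    elif params.alt_mode == "any_samples":
        fallback = detected.sum(axis=1) >= params.alt_times
        fallback_name = "clause_spread"
    else:
        per_time = detected.T.groupby(times.values).any().T
        fallback = per_time.sum(axis=1) >= params.alt_times
        fallback_name = "clause_spread"
    return pd.DataFrame(
        {
            "clause_full_replicates": full_set,
            fallback_name: fallback,
            "retained": full_set | fallback,
        }
    )


def filter_replicate_presence(
    matrix: pd.DataFrame, design: pd.DataFrame, params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Keep features seen in a full replicate set at some timepoint, or
    spread over at least ``alt_times`` distinct timepoints."""
    report = presence_report(matrix, design, params, metabolite=False)
    return matrix.loc[report["retained"]]


def normalize_metabolites(peaks: pd.DataFrame) -> pd.DataFrame:
    """Sample-centric normalization: divide by the total area of each sample.

    NaN entries (missing, to impute later) are ignored in the totals and
    propagated unchanged.
    """
    if (peaks.to_numpy() < 0).any():
        raise ParameterError("peak areas must be nonnegative")
    totals = peaks.sum(axis=0, skipna=True)
    dead = totals[totals <= 0]
    if len(dead):
        raise DegenerateSampleError(f"sample(s) with zero total area: {list(dead.index)}")
    return peaks.div(totals, axis=1)


def filter_metabolite_presence(
    matrix: pd.DataFrame, design: pd.DataFrame, params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Keep metabolites seen in a full replicate set at some timepoint, or in
    strictly more than ``metabolite_min_samples`` samples overall."""
    report = presence_report(matrix, design, params, metabolite=True)
    return matrix.loc[report["retained"]]


def normalize_physio_t0(
    values: pd.DataFrame, design: pd.DataFrame, exempt: tuple[str, ...] | list[str] = ()
) -> pd.DataFrame:
    """Express each variable relative to its mean at the first sampling time.

    Variables listed in ``exempt`` (e.g. a quantum-yield ratio that is already
    dimensionless) pass through unchanged.
    """
    _check_design(values, design)
    t0 = design.loc[values.columns, "time_h"].min()
    t0_cols = [s for s in values.columns if design.at[s, "time_h"] == t0]
    out = values.copy().astype(float)
    for var in values.index:
        if var in exempt:
            continue
        baseline = values.loc[var, t0_cols].mean()
        if baseline == 0 or np.isnan(baseline):
            raise DegenerateBaselineError(f"variable {var!r} has zero/NaN mean at T{t0}")
        out.loc[var] = values.loc[var] / baseline
    return out


_PREFIX = {"protein": "prot", "metabolite": "met", "physiology": "phys"}


def merge_blocks(
    nsaf: pd.DataFrame,
    metabolites: pd.DataFrame,
    physio: pd.DataFrame,
    design: pd.DataFrame,
) -> FeatureMatrix:
    """Row-stack the three blocks into one FeatureMatrix.

    Feature IDs are block-prefixed (``prot:``, ``met:``, ``phys:``) so they
    are globally unique even if raw IDs collide across blocks.
    """
    blocks = [
        ("protein", nsaf),
        ("metabolite", metabolites),
        ("physiology", physio),
    ]
    nonempty = [(name, frame) for name, frame in blocks if len(frame)]
    check_same_samples(*[frame for _, frame in nonempty])
    sample_order = [s for s in design.index if s in set(nonempty[0][1].columns)]
    parts, labels = [], []
    for name, frame in nonempty:
        renamed = frame.loc[:, sample_order].copy()
        renamed.index = [f"{_PREFIX[name]}:{i}" for i in frame.index]
        parts.append(renamed)
        labels.extend([name] * len(frame))
    values = pd.concat(parts, axis=0)
    return FeatureMatrix(
        values=values,
        blocks=pd.Series(labels, index=values.index, name="block"),
        design=design.loc[sample_order],
    )
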
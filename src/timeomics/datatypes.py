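"""Core in-memory containers shared by all pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

#: canonical block labels, in merge order
BLOCKS = ("protein", "metabolite", "physiology")


@dataclass
class SpectralCountTable:
    """Protein x sample spectral counts plus per-protein length.

    ``counts`` holds one row per protein and one column per sample (PSM
    counts, nonnegative); ``lengths`` gives each protein's length in
    amino-acid residues.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise SchemaError("counts and lengths must share the same protein index")
        if self.counts.index.has_duplicates:
            raise SchemaError("duplicate protein IDs in spectral count table")
        if self.counts.columns.has_duplicates:
            raise SchemaError("duplicate sample IDs in spectral count table")
        if (self.lengths < 1).any():
            bad = self.lengths.index[self.lengths < 1].tolist()
            raise SchemaError(f"protein lengths must be >= 1 residue: {bad[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError("spectral counts must be nonnegative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectralCountTable":
        """Build from a TSV-shaped frame whose first column is ``length``."""
        if "length" not in df.columns:
            raise SchemaError("spectral count table needs a 'length' column")
        lengths = df["length"].astype(int)
        counts = df.drop(columns="length")
        return cls(counts=counts, lengths=lengths)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        return out

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class FeatureMatrix:
    """Feature x sample abundance matrix with block labels and design.

    The pipeline's lingua franca: ``values`` has features in rows and samples
    in columns, ``blocks`` labels each feature as protein / metabolite /
    physiology, and ``design`` carries per-sample timepoint and replicate.
    """

    values: pd.DataFrame
    blocks: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.blocks.index.equals(self.values.index):
            raise SchemaError("block labels must be indexed by the feature index")
        unknown = set(self.blocks.unique()) - set(BLOCKS)
        if unknown:
            raise SchemaError(f"unknown block labels: {sorted(unknown)}")
        if set(self.values.columns) != set(self.design.index):
            missing = set(self.values.columns) ^ set(self.design.index)
            raise SchemaError(f"values/design sample mismatch: {sorted(missing)}")

    def block_values(self, block: str) -> pd.DataFrame:
        return self.values.loc[self.blocks == block]

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class TruthRecord:
    """Ground truth planted by the synthetic generator.

    responders: feature ID -> multiplicative profile per timepoint.
    block_memberships: feature ID -> latent-factor index.
    causal_pairs: ordered (driver, target, lag-1 coefficient) triples.
    missing_cells: (feature, sample) positions deliberately blanked.
    condition_labels: timepoint -> "control-like" | "starved-like".
    expected_psm: analytic expectation of the spectral counts (kept in memory
    for oracle tests; not serialized).
    """

    responders: dict[str, list[float]] = field(default_factory=dict)
    block_memberships: dict[str, int] = field(default_factory=dict)
    causal_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    condition_labels: dict[float, str] = field(default_factory=dict)
    expected_psm: pd.DataFrame | None = None

    def merge(self, other: "TruthRecord") -> "TruthRecord":
        merged = TruthRecord(
            responders={**self.responders, **other.responders},
            block_memberships={**self.block_memberships, **other.block_memberships},
            causal_pairs=self.causal_pairs + other.causal_pairs,
            missing_cells=self.missing_cells + other.missing_cells,
            condition_labels={**self.condition_labels, **other.condition_labels},
            expected_psm=self.expected_psm if self.expected_psm is not None else other.expected_psm,
        )
        return merged

    def to_json(self, path: str | Path) -> None:
        payload = {
            "responders": self.responders,
            "block_memberships": self.block_memberships,
            "causal_pairs": [list(p) for p in self.causal_pairs],
            "missing_cells": [list(c) for c in self.missing_cells],
            "condition_labels": {str(k): v for k, v in self.condition_labels.items()},
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            responders=payload.get("responders", {}),
            block_memberships=payload.get("block_memberships", {}),
            causal_pairs=[tuple(p) for p in payload.get("causal_pairs", [])],
            missing_cells=[tuple(c) for c in payload.get("missing_cells", [])],
            condition_labels={float(k): v for k, v in payload.get("condition_labels", {}).items()},
        )


def check_same_samples(*frames: pd.DataFrame) -> None:
    """Raise SchemaError listing the difference if sample sets differ."""
    reference = set(frames[0].columns)
    for frame in frames[1:]:
        if set(frame.columns) != reference:
            diff = sorted(reference ^ set(frame.columns))
            raise SchemaError(f"sample sets differ between blocks: {diff}")


def as_float_array(values) -> np.ndarray:
    return np.asarray(values, dtype=float)
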
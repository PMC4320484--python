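"""Tab-separated and JSON I/O shared by every stage.

All tabular files are TSV with a header row; feature tables carry features in
rows (first column = feature ID) and samples in columns. JSON is written with
sorted keys so that repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

DESIGN_COLUMNS = ("time_h", "replicate")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample table (first column = feature ID)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (sample ID, time_h, replicate)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"design table {path} lacks columns {missing}")
    df.index = df.index.astype(str)
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    design.to_csv(path, sep="\t", index_label="sample")


def read_bin_map(path: str | Path) -> pd.Series:
    """Read a two-column feature -> functional-bin TSV.

    A feature mapped to several bins (semicolon-separated) keeps the first,
    most specific assignment.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise SchemaError(f"bin map {path} needs two columns (feature, bin)")
    bins = df.iloc[:, 0].astype(str).str.split(";").str[0].str.strip()
    bins.index = bins.index.astype(str)
    return bins


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    try:
        import numpy as np

        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        if isinstance(value, np.ndarray):
            return value.tolist()
    except ImportError:  # pragma: no cover
        pass
    return str(value)
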
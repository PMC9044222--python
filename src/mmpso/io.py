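"""Delimited-text dataset I/O and JSON helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TabularDataset

__all__ = ["load_dataset", "save_dataset", "write_json", "read_json"]


def load_dataset(path, label_col: str, delimiter: str = ",") -> TabularDataset:
    """Read a header-carrying delimited table into a :class:`TabularDataset`.

    All non-label columns must parse as reals; labels become categorical
    codes (sorted unique order). Missing or unparseable cells are rejected
    with their row/column coordinates (1-based data rows, header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter)
    if label_col not in df.columns:
        raise ValueError(
            f"label column {label_col!r} not found; available: {list(df.columns)}"
        )
    labels = df[label_col]
    feats = df.drop(columns=[label_col])
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        cells = [
            (int(r) + 1, c)
            for c in bad.columns
            for r in np.flatnonzero(bad[c].to_numpy())
        ]
        preview = ", ".join(f"row {r} column {c!r}" for r, c in cells[:5])
        raise ValueError(
            f"{len(cells)} missing/unparseable cell(s): {preview}"
            + ("..." if len(cells) > 5 else "")
        )
    if labels.isna().any():
        raise ValueError("missing values in the label column")
    class_names = sorted(labels.unique().tolist())
    codes = labels.map({c: i for i, c in enumerate(class_names)}).to_numpy()
    return TabularDataset(
        X=numeric.to_numpy(dtype=float),
        y=codes,
        feature_names=list(feats.columns),
        label_name=label_col,
        class_names=class_names,
    )


def save_dataset(dataset: TabularDataset, path, delimiter: str = ",") -> None:
    """Write a dataset back to delimited text (labels as original values)."""
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df[dataset.label_name] = [dataset.class_names[c] for c in dataset.y]
    df.to_csv(path, sep=delimiter, index=False)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
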
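"""Reading and writing the pipeline's file formats.

Count tables are CSV/TSV with the first column a sample identifier and
one integer column per species; group labels come either from a
designated column of the same file or from a two-column companion file
(sample, group).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_counts", "write_counts", "write_metadata"]


def read_counts(
    path,
    group_col: str | None = None,
    group_file=None,
    sep: str | None = None,
):
    """Load a count table.

    Returns ``(Y, species, samples, groups)``; groups is None when no
    grouping was supplied.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    sample_col = df.columns[0]
    df = df.set_index(sample_col)
    groups = None
    if group_col is not None:
        if group_col not in df.columns:
            raise ValueError(f"group column {group_col!r} not found in {path}")
        groups = df[group_col].to_numpy()
        df = df.drop(columns=[group_col])
    counts = df.apply(pd.to_numeric)
    if (counts.to_numpy() < 0).any() or not np.allclose(counts.to_numpy() % 1, 0):
        raise ValueError("count cells must be non-negative integers")
    Y = counts.to_numpy().astype(np.int64)
    samples = list(df.index.astype(str))
    species = list(counts.columns)
    if group_file is not None:
        gdf = pd.read_csv(group_file)
        gdf = gdf.set_index(gdf.columns[0])
        try:
            groups = gdf.iloc[:, 0].loc[samples].to_numpy()
        except KeyError as exc:
            raise ValueError(f"group file is missing samples: {exc}") from exc
    return Y, species, samples, groups


def write_counts(path, Y, species, samples=None, groups=None) -> None:
    Y = np.asarray(Y)
    if samples is None:
        samples = [f"unit{i + 1}" for i in range(Y.shape[0])]
    df = pd.DataFrame(Y, columns=species, index=pd.Index(samples, name="sample"))
    if groups is not None:
        df.insert(0, "group", np.asarray(groups))
    df.to_csv(path)


def write_metadata(path, **fields) -> None:
    """Sidecar JSON with settings, seed and provenance for a stage output."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(fields, fh, indent=1, default=default)
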
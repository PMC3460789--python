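"""In-memory containers for expression data and TSV round-trip I/O.

Two containers are shared across the pipeline:

* :class:`ExpressionDataset` — one multi-tissue voter: a genes × tissues
  intensity (or EST count) matrix, optionally paired with MAS5-style
  Present/Absent call strings of identical shape.
* :class:`StageDataset` — one developmental time course: a genes × ordered
  stages matrix in which every stage carries a spermatogenesis phase tag
  (mitotic, meiotic or post-meiotic).

On disk both are plain TSV: first column the gene id, remaining columns the
tissue/stage names.  An array dataset's calls live in a sibling file
``<name>.calls.tsv`` with the same shape and "P"/"A" entries.  Stage phase
tags travel in a small YAML/TSV sidecar handled by :mod:`e3miner.cli`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARRAY = "array"
EST_COUNTS = "est_counts"

PHASES = ("mitotic", "meiotic", "post-meiotic")


@dataclass
class ExpressionDataset:
    """One voter: genes × tissues expression values with optional P/A calls."""

    name: str
    values: pd.DataFrame
    calls: pd.DataFrame | None = None
    kind: str = ARRAY

    def __post_init__(self) -> None:
        if self.kind not in (ARRAY, EST_COUNTS):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if (np.asarray(self.values) < 0).any():
            raise ValueError(f"dataset {self.name!r} contains negative values")
        if self.kind == EST_COUNTS:
            if self.calls is not None:
                raise ValueError("EST count datasets carry no P/A calls")
            arr = np.asarray(self.values)
            if arr.size and not np.allclose(arr, np.round(arr)):
                raise ValueError("EST count datasets must hold integer counts")
        if self.calls is not None:
            if self.calls.shape != self.values.shape:
                raise ValueError(
                    f"calls shape {self.calls.shape} != values shape "
                    f"{self.values.shape} in dataset {self.name!r}"
                )
            if not (
                self.calls.index.equals(self.values.index)
                and self.calls.columns.equals(self.values.columns)
            ):
                raise ValueError("calls axes differ from values axes")
            bad = set(np.unique(self.calls.to_numpy())) - {"P", "A"}
            if bad:
                raise ValueError(f"calls contain entries outside P/A: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns


@dataclass
class StageDataset:
    """One developmental time course with phase-tagged, ordered stages."""

    name: str
    values: pd.DataFrame
    phases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("a stage dataset needs at least 2 stages")
        if len(self.phases) != self.values.shape[1]:
            raise ValueError("one phase tag per stage is required")
        for p in self.phases:
            if p not in PHASES:
                raise ValueError(f"unknown phase {p!r}; expected one of {PHASES}")
        order = [PHASES.index(p) for p in self.phases]
        if any(a > b for a, b in zip(order, order[1:])):
            raise ValueError("phase tags must be non-decreasing along the stage order")
        if (np.asarray(self.values) < 0).any():
            raise ValueError(f"dataset {self.name!r} contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> pd.Index:
        return self.values.columns


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × columns TSV matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_dataset(
    path: str | Path,
    name: str | None = None,
    kind: str = ARRAY,
    require_calls: bool = False,
) -> ExpressionDataset:
    """Load ``<path>`` and, for array data, a sibling ``<stem>.calls.tsv``.

    With ``require_calls`` an array dataset lacking its calls file is a
    validation error (used by the pipeline, which treats missing MAS5 calls
    as a configuration mistake rather than silently assuming presence).
    """
    path = Path(path)
    values = read_matrix(path)
    calls = None
    if kind == ARRAY:
        calls_path = path.with_suffix("").with_suffix("")  # strip .tsv
        calls_path = path.parent / (path.name.removesuffix(".tsv") + ".calls.tsv")
        if calls_path.exists():
            calls = read_matrix(calls_path)
        elif require_calls:
            raise FileNotFoundError(
                f"array dataset {path.name!r} has no calls file {calls_path.name!r}"
            )
    if kind == EST_COUNTS:
        values = values.astype(int)
    return ExpressionDataset(name or path.stem, values, calls, kind)


def write_expression_dataset(dataset: ExpressionDataset, directory: str | Path) -> Path:
    """Write values (and calls, if any) under ``directory``; return values path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vpath = directory / f"{dataset.name}.tsv"
    write_matrix(dataset.values, vpath)
    if dataset.calls is not None:
        write_matrix(dataset.calls, directory / f"{dataset.name}.calls.tsv")
    return vpath
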
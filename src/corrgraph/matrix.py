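"""Numeric data tables from which correlation graphs are built.

A :class:`DataMatrix` holds the numeric block of a CSV/TSV table (rows =
entities to correlate, columns = observations) plus any declared annotation
columns, which become node attributes on the correlation graph.  Missing
cells are kept as NaN and handled pairwise during correlation rather than
being imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import CATEGORICAL, NUMERIC, AttributeTable

log = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "NULL", "null"}


@dataclass
class DataMatrix:
    row_ids: list
    col_ids: list
    values: np.ndarray  # float matrix, NaN = missing
    row_annotations: AttributeTable = field(default_factory=AttributeTable)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"value block {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        for name, ids in (("row", self.row_ids), ("column", self.col_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "DataMatrix":
        """Swap rows and columns; annotations apply to rows only and are dropped."""
        if self.row_annotations.names:
            warnings.warn(
                "transpose drops row annotations: "
                + ", ".join(self.row_annotations.names)
            )
        return DataMatrix(
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            values=self.values.T.copy(),
        )

    def drop_constant_rows(self, var_tol: float = 1e-12) -> tuple["DataMatrix", list]:
        """Remove rows whose sample variance is below ``var_tol``.

        Pearson correlation is undefined for zero-variance rows, so these
        are stripped before graph construction and their ids reported.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            variances = np.nanvar(self.values, axis=1, ddof=1)
        keep = np.where(np.nan_to_num(variances, nan=0.0) >= var_tol)[0]
        keep_set = set(keep.tolist())
        removed = [r for i, r in enumerate(self.row_ids) if i not in keep_set]
        if not len(keep):
            warnings.warn("all rows are constant; empty matrix returned")
        kept_ids = [self.row_ids[i] for i in keep]
        out = DataMatrix(
            row_ids=kept_ids,
            col_ids=list(self.col_ids),
            values=self.values[keep],
            row_annotations=self.row_annotations.restrict(kept_ids),
        )
        return out, removed

    def to_csv(self, path, sep: str = ",") -> None:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        for name, col in self.row_annotations.items():
            df.insert(0, name, [col.values.get(r) for r in self.row_ids])
        df.to_csv(path, sep=sep)


def _detect_sep(path, sep):
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_matrix(
    path,
    annotation_columns: list | None = None,
    transpose: bool = False,
    sep: str | None = None,
    max_missing_frac: float = 0.5,
) -> DataMatrix:
    """Read a CSV/TSV table into a DataMatrix.

    First row = column names, first column = row names.  Columns listed in
    ``annotation_columns`` are split out as categorical row annotations.
    Rows with more than ``max_missing_frac`` missing values are dropped
    with a warning.  Non-numeric cells in the data block raise an error
    naming the offending row and column.
    """
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(r) for r in df.index]
    if len(set(row_ids)) != len(row_ids):
        dupes = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise ValueError(f"duplicate row names in {path.name}: {dupes}")

    annotation_columns = list(annotation_columns or [])
    annots = AttributeTable()
    for name in annotation_columns:
        if name not in df.columns:
            raise ValueError(f"annotation column {name!r} not found in {path.name}")
        annots.set_column(
            name, CATEGORICAL, dict(zip(row_ids, df[name].astype(str)))
        )
    data = df.drop(columns=annotation_columns)
    col_ids = [str(c) for c in data.columns]

    values = np.empty(data.shape, dtype=float)
    raw = data.to_numpy()
    for j, cname in enumerate(col_ids):
        for i in range(len(row_ids)):
            cell = raw[i, j].strip()
            if cell in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {cname!r} in {path.name}"
                ) from None

    m = DataMatrix(row_ids, col_ids, values, annots)
    if transpose:
        m = m.transpose()

    missing_frac = np.isnan(m.values).mean(axis=1)
    bad = missing_frac > max_missing_frac
    if bad.any():
        dropped = [m.row_ids[i] for i in np.where(bad)[0]]
        warnings.warn(
            f"dropping {len(dropped)} rows with >{max_missing_frac:.0%} "
            f"missing values: {dropped[:10]}"
        )
        keep_ids = [r for r, b in zip(m.row_ids, bad) if not b]
        m = DataMatrix(
            keep_ids,
            m.col_ids,
            m.values[~bad],
            m.row_annotations.restrict(keep_ids),
        )
    return m


def numeric_annotation(matrix: DataMatrix, name: str, values: dict) -> None:
    """Attach a numeric per-row annotation (e.g. a quality score)."""
    matrix.row_annotations.set_column(name, NUMERIC, values)
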
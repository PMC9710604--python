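"""Expression-matrix and sample-metadata I/O.

The in-memory convention is samples x genes everywhere; files stored
genes x samples are transposed at the boundary.  Expression values are
expected to be (or to be brought to) log scale; missing values are a hard
error rather than imputed, because the location-scale batch model has no
missingness mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "read_expression",
    "write_expression",
    "read_metadata",
    "align",
    "log_transform",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A samples x genes numeric matrix with sample and gene identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Log-scale expression values; must be finite.
    sample_ids : list of str
        Unique, ordered sample identifiers (rows).
    gene_ids : list of str
        Unique, ordered gene identifiers (columns).
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise DataError(f"expression values must be 2-D, got {self.values.ndim}-D")
        n, g = self.values.shape
        if n != len(self.sample_ids):
            raise DataError(
                f"{len(self.sample_ids)} sample ids but {n} rows of values"
            )
        if g != len(self.gene_ids):
            raise DataError(f"{len(self.gene_ids)} gene ids but {g} columns of values")
        for kind, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise DataError(f"duplicate {kind} ids: {dupes}")
        if self.values.size and not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.sample_ids), list(self.gene_ids)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: a batch label plus covariate columns.

    ``columns`` maps a column name to a list of per-sample values;
    categorical columns hold strings, numeric columns hold floats.
    """

    sample_ids: list[str]
    columns: dict[str, list]
    batch_column: str
    numeric_columns: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in metadata")
        if self.batch_column not in self.columns:
            raise DataError(
                f"batch column {self.batch_column!r} not among metadata columns "
                f"{sorted(self.columns)}"
            )
        n = len(self.sample_ids)
        for name, vals in self.columns.items():
            if len(vals) != n:
                raise DataError(
                    f"column {name!r} has {len(vals)} values for {n} samples"
                )
        missing = [
            sid
            for sid, b in zip(self.sample_ids, self.columns[self.batch_column])
            if b is None or (isinstance(b, float) and np.isnan(b)) or str(b) == ""
        ]
        if missing:
            raise DataError(f"missing batch label for samples: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def batch_labels(self) -> list[str]:
        return [str(b) for b in self.columns[self.batch_column]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns, index=self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SampleMetadata(
            sample_ids=list(sample_ids),
            columns={k: [v[i] for i in idx] for k, v in self.columns.items()},
            batch_column=self.batch_column,
            numeric_columns=set(self.numeric_columns),
        )


def read_expression(
    path,
    orientation: str = "samples_by_genes",
    delimiter: str = ",",
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The first column holds row identifiers and the header row holds column
    identifiers.  ``orientation`` declares what the file's rows mean; the
    result is always samples x genes.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's parser round-trips float64 exactly (pandas' fast
            # parser does not)
            body[:, j] = np.asarray(df[col].to_numpy(), dtype=float)
        except (ValueError, TypeError):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"non-numeric cell {cell!r} at row {df.index[i]!r}, "
                        f"column {col!r} in {path}"
                    ) from None
            raise
    if not np.isfinite(body).all() and body.size:
        i, j = np.argwhere(~np.isfinite(body))[0]
        raise DataError(
            f"non-finite value at row {df.index[i]!r}, column {df.columns[j]!r} "
            f"in {path}"
        )
    if orientation == "genes_by_samples":
        return ExpressionMatrix(body.T, list(df.columns), list(df.index))
    return ExpressionMatrix(body, list(df.index), list(df.columns))


def write_expression(m: ExpressionMatrix, path, delimiter: str = ",") -> None:
    """Write samples x genes CSV/TSV; round-trips at full float precision."""
    df = m.to_frame()
    df.to_csv(path, sep=delimiter, float_format="%.17g", index_label="sample")


def read_metadata(
    path,
    sample_id_column: str,
    batch_column: str,
    numeric_columns: list[str] | None = None,
    delimiter: str = ",",
) -> SampleMetadata:
    """Read a per-sample metadata table.

    Columns other than ``numeric_columns`` are stored as strings (categorical).
    """
    numeric_columns = list(numeric_columns or [])
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in (sample_id_column, batch_column, *numeric_columns):
        if col not in df.columns:
            raise DataError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    sample_ids = [str(s) for s in df[sample_id_column]]
    columns: dict[str, list] = {}
    for col in df.columns:
        if col == sample_id_column:
            continue
        if col in numeric_columns:
            try:
                columns[col] = [float(v) for v in df[col]]
            except ValueError as e:
                raise DataError(f"non-numeric value in declared numeric column {col!r}: {e}")
        else:
            columns[col] = [str(v) for v in df[col]]
    empty = [sid for sid, b in zip(sample_ids, columns[batch_column]) if str(b) == ""]
    if empty:
        raise DataError(f"missing batch label for samples: {empty}")
    return SampleMetadata(
        sample_ids=sample_ids,
        columns=columns,
        batch_column=batch_column,
        numeric_columns=set(numeric_columns),
    )


def align(
    m: ExpressionMatrix, meta: SampleMetadata
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Restrict matrix and metadata to their common samples, in matrix order.

    Warns listing samples dropped from either side; errors if the
    intersection is empty.
    """
    meta_set = set(meta.sample_ids)
    keep = [s for s in m.sample_ids if s in meta_set]
    if not keep:
        raise DataError("expression matrix and metadata share no sample ids")
    dropped_m = [s for s in m.sample_ids if s not in meta_set]
    keep_set = set(keep)
    dropped_meta = [s for s in meta.sample_ids if s not in keep_set]
    if dropped_m or dropped_meta:
        warnings.warn(
            f"align dropped {len(dropped_m)} matrix-only samples {dropped_m} and "
            f"{len(dropped_meta)} metadata-only samples {dropped_meta}",
            stacklevel=2,
        )
    if keep == m.sample_ids and meta.sample_ids == keep:
        return m, meta
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    mat = ExpressionMatrix(
        m.values[[pos[s] for s in keep]], keep, list(m.gene_ids)
    )
    return mat, meta.subset(keep)


def log_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise natural log of (value + offset)."""
    shifted = m.values + offset
    if m.values.size and shifted.min() <= 0:
        raise DataError(
            f"log_transform requires value + offset > 0; minimum is "
            f"{m.values.min()} + {offset} = {shifted.min()}"
        )
    return ExpressionMatrix(np.log(shifted), list(m.sample_ids), list(m.gene_ids))
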
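"""Model-matrix construction and rank diagnostics.

The encoded design stacks [batch one-hots | desired covariates | unwanted
covariates].  Categorical covariates are expanded to *full* one-hot blocks
(no reference level dropped): with a full batch block each extra full
categorical block introduces an exact linear dependency, which is the
rank-deficient regime the regularized fit is built for.  Numeric covariates
are z-scored so the penalties act on comparable scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import SampleMetadata

__all__ = [
    "DesignSpec",
    "EncodedDesign",
    "RankReport",
    "encode_design",
    "zero_hops",
    "rank_diagnostics",
]


@dataclass
class DesignSpec:
    """Which metadata columns play which role in the model.

    ``desired_columns`` carry biology to preserve (design X); known
    nuisance covariates go in ``unwanted_columns`` (C); names listed in
    ``numeric_columns`` are treated as continuous, all others as categorical.
    """

    batch_column: str
    desired_columns: list[str] = field(default_factory=list)
    unwanted_columns: list[str] = field(default_factory=list)
    numeric_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.batch_column in set(self.desired_columns) | set(self.unwanted_columns):
            raise ValueError(
                f"batch column {self.batch_column!r} may not also be a covariate"
            )
        overlap = set(self.desired_columns) & set(self.unwanted_columns)
        if overlap:
            raise ValueError(f"columns in both desired and unwanted: {sorted(overlap)}")

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            batch_column=d["batch_column"],
            desired_columns=list(d.get("desired_columns", [])),
            unwanted_columns=list(d.get("unwanted_columns", [])),
            numeric_columns=list(d.get("numeric_columns", [])),
        )

    def to_dict(self) -> dict:
        return {
            "batch_column": self.batch_column,
            "desired_columns": list(self.desired_columns),
            "unwanted_columns": list(self.unwanted_columns),
            "numeric_columns": list(self.numeric_columns),
        }


@dataclass
class EncodedDesign:
    """Assembled model matrix with per-column provenance.

    ``column_roles`` tags each column as 'batch', 'desired' or 'unwanted';
    ``category_maps`` records, for each categorical source column, the ordered
    level -> encoded-column-index mapping.
    """

    matrix: np.ndarray
    column_roles: list[str]
    column_names: list[str]
    batch_labels: list[str]
    batch_names: list[str]
    batch_sizes: dict[str, int]
    category_maps: dict[str, dict[str, int]]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_batches(self) -> int:
        return len(self.batch_names)

    def columns_with_role(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.column_roles) if r == role], dtype=int)

    @property
    def batch_block(self) -> np.ndarray:
        return self.matrix[:, self.columns_with_role("batch")]

    @property
    def batch_index(self) -> np.ndarray:
        """Per-sample integer batch index into ``batch_names``."""
        pos = {b: i for i, b in enumerate(self.batch_names)}
        return np.array([pos[b] for b in self.batch_labels], dtype=int)

    def fingerprint(self) -> tuple:
        return (self.n, self.m, tuple(self.column_roles), tuple(self.batch_names))


@dataclass
class RankReport:
    rank: int
    m: int
    is_singular: bool
    condition_number: float
    null_space_witness: list[int] | None = None

    def __str__(self) -> str:
        state = "SINGULAR" if self.is_singular else "full rank"
        msg = (
            f"design matrix: {state} (rank {self.rank} of {self.m} columns, "
            f"condition number {self.condition_number:.3g})"
        )
        if self.null_space_witness:
            msg += f"; columns in a linear dependency: {self.null_space_witness}"
        return msg


def _one_hot(values: list[str]) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(values))
    pos = {v: i for i, v in enumerate(levels)}
    block = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        block[i, pos[v]] = 1.0
    return block, levels


def encode_design(meta: SampleMetadata, spec: DesignSpec) -> EncodedDesign:
    """Build the model matrix [batch one-hots | desired | unwanted].

    Categorical columns become full one-hot blocks with levels in
    lexicographic order; numeric columns are standardized to zero mean and
    unit variance.  Deterministic given the metadata.
    """
    for col in [*spec.desired_columns, *spec.unwanted_columns]:
        if col not in meta.columns:
            raise ValueError(
                f"design column {col!r} not in metadata columns {sorted(meta.columns)}"
            )
    numeric = set(spec.numeric_columns) | set(meta.numeric_columns)

    batch_block, batch_names = _one_hot(meta.batch_labels)
    blocks = [batch_block]
    roles = ["batch"] * batch_block.shape[1]
    names = [f"batch={b}" for b in batch_names]
    category_maps: dict[str, dict[str, int]] = {
        meta.batch_column: {b: i for i, b in enumerate(batch_names)}
    }

    for role, cols in (("desired", spec.desired_columns), ("unwanted", spec.unwanted_columns)):
        for col in cols:
            vals = meta.columns[col]
            if col in numeric:
                x = np.asarray(vals, dtype=float)
                sd = x.std()
                if sd == 0:
                    warnings.warn(f"numeric column {col!r} is constant", stacklevel=2)
                    z = np.zeros_like(x)
                else:
                    z = (x - x.mean()) / sd
                blocks.append(z[:, None])
                roles.append(role)
                names.append(col)
            else:
                svals = [str(v) for v in vals]
                if len(set(svals)) == 1:
                    warnings.warn(
                        f"categorical column {col!r} has a single level; its "
                        "one-hot block is constant",
                        stacklevel=2,
                    )
                block, levels = _one_hot(svals)
                offset = sum(b.shape[1] for b in blocks)
                category_maps[col] = {lv: offset + i for i, lv in enumerate(levels)}
                blocks.append(block)
                roles.extend([role] * block.shape[1])
                names.extend(f"{col}={lv}" for lv in levels)

    matrix = np.hstack(blocks) if blocks else np.empty((meta.n_samples, 0))
    batch_sizes = {b: int(batch_block[:, i].sum()) for i, b in enumerate(batch_names)}
    return EncodedDesign(
        matrix=matrix,
        column_roles=roles,
        column_names=names,
        batch_labels=meta.batch_labels,
        batch_names=batch_names,
        batch_sizes=batch_sizes,
        category_maps=category_maps,
    )


def zero_hops(meta: SampleMetadata, spec: DesignSpec) -> list[str]:
    """Group samples sharing the exact same biological design.

    Two samples get the same label iff they agree on every desired column;
    batch and unwanted columns are ignored.  Labels are canonical
    'col=value|col=value' strings over the sorted desired columns, so the
    grouping is invariant under sample permutation and batch renaming.
    """
    if not spec.desired_columns:
        raise ValueError("zero_hops requires at least one desired column")
    cols = sorted(spec.desired_columns)
    labels = []
    for i in range(meta.n_samples):
        parts = [f"{c}={meta.columns[c][i]}" for c in cols]
        labels.append("|".join(parts))
    return labels


def rank_diagnostics(d: EncodedDesign, rtol: float | None = None) -> RankReport:
    """Numerical rank of the encoded design by SVD.

    Rank counts singular values above ``rtol * s_max`` with the standard
    convention rtol = max(n, m) * machine epsilon; the condition number is
    the ratio of extreme retained singular values.  When singular, a
    null-space witness lists the columns with non-negligible weight in the
    smallest right singular vector.
    """
    X = d.matrix
    n, m = X.shape
    if m == 0:
        return RankReport(rank=0, m=0, is_singular=False, condition_number=1.0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if rtol is None:
        rtol = max(n, m) * np.finfo(float).eps
    tol = rtol * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    is_singular = rank < m
    if rank == 0:
        cond = np.inf
    else:
        cond = float(s[0] / s[rank - 1])
    witness = None
    if is_singular:
        v = Vt[-1]
        witness = [int(i) for i in np.nonzero(np.abs(v) > 1e-8)[0]]
    return RankReport(
        rank=rank, m=m, is_singular=is_singular, condition_number=cond,
        null_space_witness=witness,
    )
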
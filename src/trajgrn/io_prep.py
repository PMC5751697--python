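"""Loading, validation, shift transformation and filtering of expression matrices.

Relative expression values from single-cell qPCR (dCt units) are mostly
negative; the downstream ODE model assumes nonnegative state variables,
so each gene's profile is shifted so that its minimum is exactly zero.
Housekeeping (reference) genes and genes with negligible variation carry
no trajectory signal and are removed before network inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ShiftedMatrix",
    "load_expression_matrix",
    "shift_to_nonnegative",
    "filter_genes",
]


class ValidationError(ValueError):
    """Structural problem in an input table (duplicate/missing identifiers)."""


class ParseError(ValueError):
    """A cell of the input table could not be parsed as a number."""


@dataclass
class ExpressionMatrix:
    """A genes x cells real matrix with identifiers and housekeeping flags.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Relative expression (dCt); may be negative.
    gene_ids, cell_ids : list of str
        Unique row / column identifiers, in file order.
    housekeeping : ndarray of bool, shape (n_genes,)
        True for reference genes to be excluded from inference.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    housekeeping: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.housekeeping = np.asarray(self.housekeeping, dtype=bool)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValidationError("identifier lists do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if self.housekeeping.shape != (n_genes,):
            raise ValidationError("housekeeping flag vector has wrong length")
        if not np.isfinite(self.values).all():
            raise ValidationError("matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ShiftedMatrix(ExpressionMatrix):
    """Expression matrix after the per-gene shift; every row minimum is 0.

    ``offsets[i]`` is the value subtracted from gene i, i.e. the original
    row minimum.
    """

    offsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.offsets = np.asarray(self.offsets, dtype=float)

    def offsets_json(self) -> str:
        """Serialize the applied offsets (and the convention used) as JSON."""
        payload = {
            "convention": "subtract-row-minimum",
            "offsets": dict(zip(self.gene_ids, self.offsets.tolist())),
        }
        return json.dumps(payload, indent=2)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def load_expression_matrix(path: str | Path, annotation: str | Path) -> ExpressionMatrix:
    """Load a delimited genes x cells matrix plus a housekeeping annotation.

    The matrix file has a header row of cell ids and a leading gene-id
    column; the annotation maps ``gene_id`` to a 0/1 ``housekeeping``
    flag. Row and column order is preserved from the file.

    Raises
    ------
    ValidationError
        For duplicate/missing identifiers or genes absent from the
        annotation.
    ParseError
        For an empty or non-numeric cell, naming its row and column.
    """
    raw = _read_table(path)
    gene_ids = [str(g) for g in raw.index]
    cell_ids = [str(c) for c in raw.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValidationError(f"duplicate gene id(s): {dup}")
    if len(set(cell_ids)) != len(cell_ids):
        dup = sorted({c for c in cell_ids if cell_ids.count(c) > 1})
        raise ValidationError(f"duplicate cell id(s): {dup}")

    values = np.empty(raw.shape, dtype=float)
    for i, gene in enumerate(gene_ids):
        for j, cell in enumerate(cell_ids):
            entry = raw.iat[i, j]
            if entry is None or (isinstance(entry, float) and np.isnan(entry)) \
                    or str(entry).strip() == "":
                raise ParseError(f"empty value at gene {gene!r}, cell {cell!r}")
            try:
                values[i, j] = float(entry)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"non-numeric value {entry!r} at gene {gene!r}, cell {cell!r}"
                ) from exc

    ann = _read_table(annotation)
    if "housekeeping" not in ann.columns:
        raise ValidationError("annotation must have a 'housekeeping' column")
    flags = ann["housekeeping"].astype(int).astype(bool)
    missing = [g for g in gene_ids if g not in flags.index]
    if missing:
        raise ValidationError(f"gene(s) missing from annotation: {missing}")
    housekeeping = np.array([flags[g] for g in gene_ids], dtype=bool)

    return ExpressionMatrix(values, gene_ids, cell_ids, housekeeping)


def shift_to_nonnegative(m: ExpressionMatrix) -> ShiftedMatrix:
    """Shift each gene so its minimum expression is exactly zero.

    Subtracts the per-gene minimum. When the minimum is negative (the
    common case for dCt data) this equals adding its absolute value; when
    the minimum is positive, subtraction still zeroes it. Idempotent.
    """
    offsets = m.values.min(axis=1)
    shifted = m.values - offsets[:, None]
    # Guard against -0.0 / roundoff: minimum must be exactly 0 per row.
    shifted[np.arange(m.n_genes), m.values.argmin(axis=1)] = 0.0
    shifted = np.maximum(shifted, 0.0)
    return ShiftedMatrix(
        values=shifted,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        housekeeping=m.housekeeping.copy(),
        offsets=offsets,
    )


def filter_genes(
    m: ExpressionMatrix,
    exclude_ids: Sequence[str] = (),
    variance_floor: float = 0.0,
) -> ExpressionMatrix:
    """Drop housekeeping genes, explicitly excluded genes and flat genes.

    A gene is removed if it is housekeeping-flagged, listed in
    ``exclude_ids``, or has variance strictly below ``variance_floor``.
    Surviving genes keep their original order.
    """
    unknown = [g for g in exclude_ids if g not in m.gene_ids]
    if unknown:
        raise ValidationError(f"unknown gene id(s) in exclude_ids: {unknown}")
    exclude = set(exclude_ids)
    variances = m.values.var(axis=1)
    keep = [
        i
        for i, g in enumerate(m.gene_ids)
        if not m.housekeeping[i] and g not in exclude and variances[i] >= variance_floor
    ]
    cls = ShiftedMatrix if isinstance(m, ShiftedMatrix) else ExpressionMatrix
    kwargs = {}
    if cls is ShiftedMatrix:
        kwargs["offsets"] = m.offsets[keep]  # type: ignore[attr-defined]
    return cls(
        values=m.values[keep],
        gene_ids=[m.gene_ids[i] for i in keep],
        cell_ids=list(m.cell_ids),
        housekeeping=m.housekeeping[keep],
        **kwargs,
    )
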
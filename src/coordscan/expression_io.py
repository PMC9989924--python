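"""Reading, validating, normalizing and filtering gene × sample expression matrices.

The canonical on-disk format is a UTF-8 tab-separated table with genes in
rows and samples in columns; the first header cell is ignored. An optional
sample-sheet TSV (columns ``sample_id``, ``condition``) attaches per-sample
condition labels; samples not listed default to ``"unknown"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CONDITIONS = ("control", "treated", "unknown")
VALID_UNITS = ("counts", "normalized")


class ExpressionIOError(ValueError):
    """Raised for malformed expression input."""


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with per-sample condition labels.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, one per gene.
    sample_ids : sequence of str
        Unique column identifiers, one per sample.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values.
    condition : sequence of str, optional
        One of ``control``/``treated``/``unknown`` per sample.
    units : {"counts", "normalized"}
        Whether ``values`` are raw counts or already normalized; controls
        whether log-normalization is applied downstream.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    condition: tuple[str, ...] = field(default=())
    units: str = "normalized"

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.condition:
            self.condition = ("unknown",) * len(self.sample_ids)
        self.condition = tuple(self.condition)

        dup = _duplicates(self.gene_ids)
        if dup:
            raise ExpressionIOError(f"duplicate gene id(s): {', '.join(sorted(dup))}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ExpressionIOError(f"duplicate sample id(s): {', '.join(sorted(dup))}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionIOError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionIOError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if len(self.condition) != len(self.sample_ids):
            raise ExpressionIOError("condition length does not match sample count")
        for c in self.condition:
            if c not in VALID_CONDITIONS:
                raise ExpressionIOError(
                    f"invalid condition {c!r}; expected one of {VALID_CONDITIONS}"
                )
        if self.units not in VALID_UNITS:
            raise ExpressionIOError(f"invalid units {self.units!r}; expected one of {VALID_UNITS}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_samples(self, keep: Sequence[bool]) -> "ExpressionMatrix":
        keep = np.asarray(keep, dtype=bool)
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            sample_ids=tuple(s for s, k in zip(self.sample_ids, keep) if k),
            values=self.values[:, keep],
            condition=tuple(c for c, k in zip(self.condition, keep) if k),
            units=self.units,
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def load_expression(
    path: str | Path,
    transpose: bool = False,
    sample_sheet: str | Path | None = None,
    units: str = "normalized",
) -> ExpressionMatrix:
    """Load an expression TSV (genes × samples; ``transpose=True`` for the other dialect).

    Raises :class:`ExpressionIOError` for duplicate ids (naming the offender),
    non-numeric cells (naming row and column), or fewer than 3 samples.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    raw.index = raw.index.map(str)
    raw.columns = raw.columns.map(str)
    if transpose:
        raw = raw.T

    dup = _duplicates(list(raw.index))
    if dup:
        raise ExpressionIOError(
            f"duplicate gene id(s) in {path.name}: {', '.join(sorted(dup))}"
        )
    dup = _duplicates(list(raw.columns))
    if dup:
        raise ExpressionIOError(
            f"duplicate sample id(s) in {path.name}: {', '.join(sorted(dup))}"
        )

    try:
        values = raw.astype(np.float64).to_numpy()
    except (ValueError, TypeError):
        for gene, row in raw.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ExpressionIOError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise  # pragma: no cover - conversion failed but every cell parses

    if raw.shape[1] < 3:
        raise ExpressionIOError(
            f"{path.name} has {raw.shape[1]} samples; at least 3 are required"
        )

    condition: tuple[str, ...] = ()
    if sample_sheet is not None:
        condition = _read_sample_sheet(sample_sheet, tuple(raw.columns))

    return ExpressionMatrix(
        gene_ids=tuple(raw.index),
        sample_ids=tuple(raw.columns),
        values=values,
        condition=condition,
        units=units,
    )


def _read_sample_sheet(path: str | Path, sample_ids: tuple[str, ...]) -> tuple[str, ...]:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(sheet.columns):
        raise ExpressionIOError(
            f"sample sheet {Path(path).name} must have columns sample_id, condition"
        )
    mapping = dict(zip(sheet["sample_id"].map(str), sheet["condition"].map(str)))
    labels = []
    for sid in sample_ids:
        lab = mapping.get(sid, "unknown")
        if lab not in VALID_CONDITIONS:
            raise ExpressionIOError(
                f"invalid condition {lab!r} for sample {sid!r}; "
                f"expected one of {VALID_CONDITIONS}"
            )
        labels.append(lab)
    return tuple(labels)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    sample_sheet: str | Path | None = None,
) -> None:
    """Write the matrix as TSV; floats use ``repr`` so a reload is bitwise-identical."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    if sample_sheet is not None:
        pd.DataFrame(
            {"sample_id": list(matrix.sample_ids), "condition": list(matrix.condition)}
        ).to_csv(sample_sheet, sep="\t", index=False)


def normalize_log(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace each value x with log2(x + pseudocount). Requires x >= 0."""
    if pseudocount <= 0:
        raise ExpressionIOError(f"pseudocount must be positive, got {pseudocount}")
    if np.any(matrix.values < 0):
        g, s = np.argwhere(matrix.values < 0)[0]
        raise ExpressionIOError(
            f"negative value at gene {matrix.gene_ids[g]!r}, "
            f"sample {matrix.sample_ids[s]!r}; log normalization requires values >= 0"
        )
    return replace(matrix, values=np.log2(matrix.values + pseudocount), units="normalized")


def filter_invariant_genes(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose values are constant across samples (Pearson undefined).

    Returns the filtered matrix and the list of removed gene ids. Raises if
    every gene is constant.
    """
    variable = np.ptp(matrix.values, axis=1) > 0
    removed = [g for g, keep in zip(matrix.gene_ids, variable) if not keep]
    if not np.any(variable):
        raise ExpressionIOError("all genes have zero variance; nothing left to analyze")
    if removed:
        logger.info("removed %d zero-variance gene(s): %s", len(removed), ", ".join(removed))
    filtered = ExpressionMatrix(
        gene_ids=tuple(g for g, keep in zip(matrix.gene_ids, variable) if keep),
        sample_ids=matrix.sample_ids,
        values=matrix.values[variable],
        condition=matrix.condition,
        units=matrix.units,
    )
    return filtered, removed
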
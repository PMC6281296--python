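"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats: Matrix Market (MTX) with companion gene/cell name
files, dense TSV matrices (header row of column ids, first column of row
ids), GMT-style regulon files (name, TF, targets, tab-delimited) and
annotation TSVs with a ``cell_id  tissue  cell_type  [cluster]`` header.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ActivityMatrix,
    CellAnnotation,
    ExpressionMatrix,
    FormatError,
    Regulon,
    RegulonSet,
    SpecificityMatrix,
)

logger = logging.getLogger(__name__)


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX + name files or a dense TSV.

    MTX orientation (genes x cells vs cells x genes) is resolved against
    the lengths of the name files; the returned matrix is always cells x
    genes.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("MTX input requires gene and cell name files")
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_names(genes_path)
        cells = _read_names(cells_path)
        if mat.shape == (len(cells), len(genes)):
            pass
        elif mat.shape == (len(genes), len(cells)):
            mat = mat.T
        else:
            raise FormatError(
                f"{matrix_path} has shape {mat.shape}, which matches neither "
                f"{len(cells)} cells ({cells_path}) x {len(genes)} genes "
                f"({genes_path}) nor its transpose"
            )
        return ExpressionMatrix(mat, cells, genes)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{matrix_path} has no gene columns")
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(c) for c in df.index], [str(g) for g in df.columns]
    )


def read_regulons(path: str | Path) -> RegulonSet:
    """Read a GMT-style regulon file: name, TF gene, then targets per line."""
    regulons: list[Regulon] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected name, TF and >=1 target"
                )
            name, tf, *targets = fields
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate regulon name {name!r}")
            seen.add(name)
            unique = frozenset(t for t in targets if t)
            if len(unique) < len([t for t in targets if t]):
                logger.warning(
                    "regulon %s: %d duplicate targets collapsed",
                    name,
                    len(targets) - len(unique),
                )
            if not unique:
                raise FormatError(f"{path}:{lineno}: regulon {name!r} has no targets")
            regulons.append(Regulon(name=name, tf=tf, targets=unique))
    return RegulonSet(regulons)


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regulons:
            fh.write("\t".join([r.name, r.tf, *sorted(r.targets)]) + "\n")


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise FormatError(f"{path} lacks a cell_id column")
    return CellAnnotation(df)


def write_annotation(annotation: CellAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="cell_id")


def _write_table(
    values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str], path: str | Path
) -> None:
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.17g", index_label="id"
    )


def write_matrix(
    matrix: ExpressionMatrix | ActivityMatrix | SpecificityMatrix, path: str | Path
) -> None:
    """Write any matrix container to a dense TSV (rows x columns)."""
    if isinstance(matrix, ExpressionMatrix):
        _write_table(matrix.values, matrix.cell_ids, matrix.gene_ids, path)
    elif isinstance(matrix, ActivityMatrix):
        _write_table(matrix.values, matrix.unit_ids, matrix.regulon_names, path)
    elif isinstance(matrix, SpecificityMatrix):
        _write_table(matrix.values, matrix.cell_types, matrix.regulon_names, path)
    else:
        raise TypeError(f"cannot write {type(matrix).__name__}")


def _read_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no observations")
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def read_activity(path: str | Path, kind: str = "raw_auc") -> ActivityMatrix:
    values, rows, cols = _read_table(path)
    return ActivityMatrix(values, rows, cols, kind=kind)


def read_specificity(path: str | Path) -> SpecificityMatrix:
    values, rows, cols = _read_table(path)
    return SpecificityMatrix(values, rows, cols)


def write_expression_mtx(
    expr: ExpressionMatrix, matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> None:
    """Write expression as sparse MTX (genes x cells, the common layout)."""
    sparse = scipy.sparse.csr_matrix(expr.values.T)
    scipy.io.mmwrite(str(matrix_path), sparse)
    Path(genes_path).write_text("".join(g + "\n" for g in expr.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in expr.cell_ids))
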
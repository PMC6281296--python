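"""Shared data containers for the regulon analysis pipeline.

The internal matrix convention is observations (cells, pseudocells, or
cell types) in rows and variables (genes or regulons) in columns,
everywhere. Readers are responsible for transposing external files into
this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))
        raise ValidationError(f"duplicate {what} {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Non-negative cells x genes expression values.

    Units are arbitrary (the pipeline is rank-based); the synthetic
    generator emits counts.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        self.cell_ids = _check_unique(self.cell_ids, "cell id")
        self.gene_ids = _check_unique(self.gene_ids, "gene id")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if self.values.size and np.min(self.values) < 0:
            raise ValidationError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            idx = [pos[c] for c in cell_ids]
        except KeyError as exc:
            raise KeyError(f"unknown cell id {exc.args[0]!r}") from None
        return ExpressionMatrix(self.values[idx], list(cell_ids), list(self.gene_ids))


@dataclass
class CellAnnotation:
    """Per-cell (tissue, cell type, optional cluster) labels.

    Wraps a DataFrame indexed by ``cell_id`` with columns ``tissue``,
    ``cell_type`` and optionally ``cluster``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "cell_id" in df.columns:
            df = df.set_index("cell_id")
        df.index = df.index.astype(str)
        for col in ("tissue", "cell_type"):
            if col not in df.columns:
                raise ValidationError(f"annotation is missing column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate annotation for cell {dup!r}")
        self.table = df

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def labels_for(self, cell_ids: Sequence[str], field: str = "cell_type") -> np.ndarray:
        """Label per cell, erroring on any cell without an annotation."""
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells lack annotation (first: {missing[0]!r})"
            )
        if field not in self.table.columns:
            raise KeyError(f"unknown annotation field {field!r}")
        return self.table.loc[list(cell_ids), field].to_numpy()

    def strata(self, cell_ids: Sequence[str]) -> dict[tuple[str, str], list[str]]:
        """Cells grouped by (tissue, cell_type), keys in sorted order."""
        tissues = self.labels_for(cell_ids, "tissue")
        types = self.labels_for(cell_ids, "cell_type")
        out: dict[tuple[str, str], list[str]] = {}
        for cid, ti, ct in zip(cell_ids, tissues, types):
            out.setdefault((str(ti), str(ct)), []).append(cid)
        return dict(sorted(out.items()))


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its inferred target genes."""

    name: str
    tf: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"regulon {self.name!r} has no targets")

    @property
    def genes(self) -> frozenset[str]:
        """The gene set scored for this regulon: TF plus targets."""
        return self.targets | {self.tf}


@dataclass
class RegulonSet:
    regulons: list[Regulon]

    def __post_init__(self) -> None:
        _check_unique([r.name for r in self.regulons], "regulon name")

    def __iter__(self):
        return iter(self.regulons)

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, name: str) -> Regulon:
        for r in self.regulons:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regulons]


ACTIVITY_KINDS = ("raw_auc", "zscore", "binary", "celltype_mean")


@dataclass
class ActivityMatrix:
    """Observation units x regulons activity values.

    ``kind`` records the scale: raw recovery-curve AUC in [0, 1],
    per-regulon Z scores, the binarized 0/1 companion, or per-cell-type
    mean AUC.
    """

    values: np.ndarray
    unit_ids: list[str]
    regulon_names: list[str]
    kind: str = "raw_auc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("activity values must be a 2-D matrix")
        self.unit_ids = _check_unique(self.unit_ids, "unit id")
        self.regulon_names = _check_unique(self.regulon_names, "regulon name")
        n_units, n_reg = self.values.shape
        if len(self.unit_ids) != n_units or len(self.regulon_names) != n_reg:
            raise ValidationError("id lists do not match activity matrix shape")
        if self.kind not in ACTIVITY_KINDS:
            raise ValidationError(f"unknown activity kind {self.kind!r}")
        if self.kind in ("raw_auc", "celltype_mean") and self.values.size:
            if np.min(self.values) < -1e-9 or np.max(self.values) > 1 + 1e-9:
                raise ValidationError(f"{self.kind} activity must lie in [0, 1]")
        if self.kind == "binary" and self.values.size:
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValidationError("binary activity must contain only 0 and 1")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.unit_ids, columns=self.regulon_names
        )

    def column(self, regulon: str) -> np.ndarray:
        return self.values[:, self.regulon_names.index(regulon)]


@dataclass
class SpecificityMatrix:
    """Cell types x regulons regulon specificity scores, each in [0, 1]."""

    values: np.ndarray
    cell_types: list[str]
    regulon_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_types = _check_unique(self.cell_types, "cell type")
        self.regulon_names = _check_unique(self.regulon_names, "regulon name")
        if self.values.shape != (len(self.cell_types), len(self.regulon_names)):
            raise ValidationError("id lists do not match specificity matrix shape")
        if self.values.size and (
            np.min(self.values) < -1e-9 or np.max(self.values) > 1 + 1e-9
        ):
            raise ValidationError("specificity scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_types, columns=self.regulon_names
        )
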
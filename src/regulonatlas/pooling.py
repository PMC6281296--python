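"""Avg20 pseudocell pooling.

Cells are grouped randomly and non-overlappingly within each
(tissue, cell type) stratum and each group is averaged into one
pseudocell. The default group size of 20 cells reduces sampling noise
and the downstream computational burden while keeping groups
homogeneous in annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

REMAINDER_POLICIES = ("drop", "keep_as_smaller_group")


@dataclass
class PoolingPlan:
    """Assignment of cells to pseudocells within annotation strata."""

    group_size: int
    seed: int
    remainder_policy: str
    assignments: dict[str, str]
    pseudocell_meta: pd.DataFrame  # index pseudocell_id; columns tissue, cell_type

    @property
    def pseudocell_ids(self) -> list[str]:
        return list(self.pseudocell_meta.index)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {p: [] for p in self.pseudocell_ids}
        for cell, pseudo in self.assignments.items():
            out[pseudo].append(cell)
        return out

    def annotation(self) -> CellAnnotation:
        """Pseudocell annotation inheriting each stratum's labels."""
        return CellAnnotation(self.pseudocell_meta.copy())


def make_pooling_plan(
    annotation: CellAnnotation,
    group_size: int = 20,
    seed: int = 0,
    remainder_policy: str = "drop",
    min_group_size: int | None = None,
) -> PoolingPlan:
    """Randomly partition each (tissue, cell type) stratum into groups.

    Within a stratum of n cells, floor(n / group_size) full groups are
    drawn from a random permutation. Remainder cells are dropped by
    default or kept as one smaller group; ``min_group_size`` additionally
    discards kept groups below that size. Deterministic for a fixed seed:
    strata are processed in sorted order from a single seeded generator.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if remainder_policy not in REMAINDER_POLICIES:
        raise ValueError(f"unknown remainder policy {remainder_policy!r}")
    cell_ids = annotation.cell_ids
    if not cell_ids:
        raise ValidationError("empty annotation: nothing to pool")
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    meta_rows: list[tuple[str, str, str]] = []
    for (tissue, cell_type), members in annotation.strata(cell_ids).items():
        members = sorted(members)
        perm = rng.permutation(len(members))
        n_full = len(members) // group_size
        groups = [
            [members[i] for i in perm[g * group_size : (g + 1) * group_size]]
            for g in range(n_full)
        ]
        remainder = [members[i] for i in perm[n_full * group_size :]]
        if remainder and remainder_policy == "keep_as_smaller_group":
            if min_group_size is None or len(remainder) >= min_group_size:
                groups.append(remainder)
        if not groups:
            logger.info(
                "stratum (%s, %s): %d cells < group size %d, no pseudocells",
                tissue, cell_type, len(members), group_size,
            )
        for g_idx, group in enumerate(groups):
            pseudo = f"{tissue}|{cell_type}|{g_idx}"
            meta_rows.append((pseudo, tissue, cell_type))
            for cell in group:
                assignments[cell] = pseudo
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "tissue", "cell_type"]
    ).set_index("cell_id")
    return PoolingPlan(
        group_size=group_size,
        seed=seed,
        remainder_policy=remainder_policy,
        assignments=assignments,
        pseudocell_meta=meta,
    )


def pool_expression(expr: ExpressionMatrix, plan: PoolingPlan) -> ExpressionMatrix:
    """Average each pseudocell's member cells into one row."""
    pos = {c: i for i, c in enumerate(expr.cell_ids)}
    unknown = [c for c in plan.assignments if c not in pos]
    if unknown:
        raise ValidationError(
            f"pooling plan references {len(unknown)} cells absent from the "
            f"matrix (first: {unknown[0]!r})"
        )
    members = plan.members()
    pooled = np.empty((len(members), expr.n_genes), dtype=float)
    ids = plan.pseudocell_ids
    for row, pseudo in enumerate(ids):
        idx = [pos[c] for c in members[pseudo]]
        pooled[row] = expr.values[idx].mean(axis=0)
    return ExpressionMatrix(pooled, ids, list(expr.gene_ids))
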
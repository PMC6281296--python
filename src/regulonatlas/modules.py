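"""Combinatorial regulon modules via the Connection Specificity Index.

Transcription factors act in combination; regulons with correlated
activity across the atlas form modules. Raw Pearson correlation is a
noisy module signal, so pairwise correlations are converted to the
Connection Specificity Index: CSI(A, B) is the fraction of the other
regulons whose correlation with both A and B falls below the
correlation between A and B. Hierarchical clustering of the CSI matrix
(Euclidean distance, average linkage) yields the modules; CSI > 0.7
defines the regulon association network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy

from .datatypes import ActivityMatrix, CellAnnotation, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """Module label per regulon plus the clustering parameters used."""

    module_of: dict[str, str]
    n_modules: int
    linkage_method: str = "average"
    metric: str = "euclidean"

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for reg, mod in self.module_of.items():
            out.setdefault(mod, []).append(reg)
        return {m: sorted(v) for m, v in sorted(out.items())}


def pairwise_pcc(activity: ActivityMatrix) -> pd.DataFrame:
    """Pearson correlation between regulon activity columns.

    Zero-variance regulons are dropped with a warning; fewer than 3
    observation units is an error.
    """
    if activity.n_units < 3:
        raise ValueError("pairwise correlation needs at least 3 units")
    sd = activity.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d zero-variance regulons dropped from PCC",
                       int((~keep).sum()))
    names = [n for n, k in zip(activity.regulon_names, keep) if k]
    if len(names) < 2:
        raise ValueError("fewer than 2 regulons with non-zero variance")
    corr = np.corrcoef(activity.values[:, keep], rowvar=False)
    return pd.DataFrame(corr, index=names, columns=names)


def csi(pcc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Connection Specificity Index of every regulon pair.

    CSI(A, B) = |{C not in {A, B} : PCC(A, C) < PCC(A, B) and
    PCC(B, C) < PCC(A, B)}| / (N - 2), with CSI(A, A) = 1 by
    convention. Strict inequalities; both conditions required.
    """
    P = np.asarray(pcc_matrix, dtype=float)
    n = P.shape[0]
    if P.shape != (n, n) or n < 3:
        raise ValueError("CSI needs a square PCC matrix over >= 3 regulons")
    if not np.allclose(P, P.T, atol=1e-9):
        raise ValueError("PCC matrix must be symmetric")
    out = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            t = P[i, j]
            # PCC(A,A)=1 and PCC(A,B)=t never satisfy "< t", so the
            # full-row count already excludes C in {A, B}
            count = int(np.sum((P[i] < t) & (P[j] < t)))
            out[i, j] = out[j, i] = count / (n - 2)
    return pd.DataFrame(out, index=pcc_matrix.index, columns=pcc_matrix.columns)


def detect_modules(
    csi_matrix: pd.DataFrame, n_modules: int, linkage_method: str = "average"
) -> ModulePartition:
    """Cut an average-linkage Euclidean tree over CSI rows into modules.

    Regulons are sorted by name before clustering so the result is
    independent of input order; module labels M1, M2, ... follow the
    order of first appearance in that sorted list.
    """
    names = sorted(str(x) for x in csi_matrix.index)
    n = len(names)
    if not 1 <= n_modules <= n:
        raise ValueError(f"n_modules must lie in [1, {n}], got {n_modules}")
    rows = csi_matrix.loc[names, names].to_numpy(dtype=float)
    if n_modules == n:
        labels = np.arange(1, n + 1)
    else:
        link = scipy.cluster.hierarchy.linkage(rows, method=linkage_method,
                                               metric="euclidean")
        labels = scipy.cluster.hierarchy.fcluster(link, t=n_modules,
                                                  criterion="maxclust")
    relabel: dict[int, str] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = f"M{len(relabel) + 1}"
    return ModulePartition(
        module_of={name: relabel[lab] for name, lab in zip(names, labels)},
        n_modules=len(set(labels)),
        linkage_method=linkage_method,
    )


def module_activity(
    activity: ActivityMatrix,
    partition: ModulePartition,
    annotation: CellAnnotation,
    module: str,
    cell_type: str,
    celltype_label_field: str = "cell_type",
) -> float:
    """Mean activity of a module's regulons over one cell type's cells."""
    members = partition.members().get(module)
    if not members:
        raise ValueError(f"module {module!r} is empty or unknown")
    labels = annotation.labels_for(activity.unit_ids, celltype_label_field)
    in_type = labels == cell_type
    if not in_type.any():
        raise ValueError(f"cell type {cell_type!r} has no cells")
    cols = [activity.regulon_names.index(m) for m in members
            if m in activity.regulon_names]
    if not cols:
        raise ValueError(f"module {module!r} has no regulons in the activity matrix")
    return float(activity.values[np.ix_(in_type, cols)].mean())


def module_activity_table(
    activity: ActivityMatrix,
    partition: ModulePartition,
    annotation: CellAnnotation,
    celltype_label_field: str = "cell_type",
) -> pd.DataFrame:
    """Modules x cell types mean-activity table."""
    labels = annotation.labels_for(activity.unit_ids, celltype_label_field)
    cell_types = sorted(set(str(x) for x in labels))
    modules = sorted(partition.members())
    table = pd.DataFrame(index=modules, columns=cell_types, dtype=float)
    for mod in modules:
        for ct in cell_types:
            table.loc[mod, ct] = module_activity(
                activity, partition, annotation, mod, ct, celltype_label_field
            )
    return table


def regulon_association_network(
    csi_matrix: pd.DataFrame, cutoff: float = 0.7
) -> pd.DataFrame:
    """Undirected edge list of regulon pairs with CSI strictly above cutoff.

    Returns a 3-column frame (regulon_a, regulon_b, csi), one row per
    unordered pair, self-edges excluded.
    """
    names = [str(x) for x in csi_matrix.index]
    values = csi_matrix.to_numpy(dtype=float)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if values[i, j] > cutoff:
                rows.append((names[i], names[j], float(values[i, j])))
    return pd.DataFrame(rows, columns=["regulon_a", "regulon_b", "csi"])
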
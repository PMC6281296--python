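"""Regulon specificity scores from Jensen-Shannon divergence.

A regulon's activity over n cells, normalized to sum to 1, is compared
against the normalized indicator distribution of a cell type. The
Jensen-Shannon divergence between the two distributions (base-2
entropy, so JSD lies in [0, 1]) is converted to a similarity:

    RSS(R, C) = 1 - JSD(P_R, P_C)

RSS = 1 means the regulon is active exactly and uniformly in the cells
of the type; RSS near 0 means the two distributions have essentially
disjoint support. Ranking regulons by RSS within a cell type surfaces
candidate critical regulators of that type's identity.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import ActivityMatrix, CellAnnotation, SpecificityMatrix

logger = logging.getLogger(__name__)


def normalize_to_distribution(v: np.ndarray) -> np.ndarray:
    """Scale a non-negative vector to sum to 1."""
    v = np.asarray(v, dtype=float)
    if v.size and np.min(v) < 0:
        raise ValueError("cannot normalize a vector with negative entries")
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate distribution: vector sums to zero")
    return v / total


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 * log2(0) = 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in [0, 1] (base-2 entropy).

    H((p+q)/2) - (H(p) + H(q)) / 2, clipped against floating-point
    drift. 0 for identical distributions, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    m = (p + q) / 2.0
    value = shannon_entropy(m) - (shannon_entropy(p) + shannon_entropy(q)) / 2.0
    return float(np.clip(value, 0.0, 1.0))


def rss(
    activity: ActivityMatrix,
    annotation: CellAnnotation,
    celltype_label_field: str = "cell_type",
) -> SpecificityMatrix:
    """Cell types x regulons specificity matrix.

    Uses the raw (non-negative) activity, not Z scores: the
    normalization to a probability distribution presupposes
    non-negative mass. Regulons whose activity is zero in every cell
    have no defined distribution and are dropped with a warning.
    """
    if activity.kind not in ("raw_auc", "celltype_mean"):
        raise ValueError("specificity requires raw (non-negative) activity")
    labels = annotation.labels_for(activity.unit_ids, celltype_label_field)
    cell_types = sorted(set(str(x) for x in labels))
    kept: list[int] = []
    for j, name in enumerate(activity.regulon_names):
        if activity.values[:, j].sum() > 0:
            kept.append(j)
        else:
            logger.warning("regulon %s inactive everywhere; RSS undefined, dropped",
                           name)
    if not kept:
        raise ValueError("no regulon with non-zero activity")
    values = np.empty((len(cell_types), len(kept)), dtype=float)
    p_reg = activity.values[:, kept] / activity.values[:, kept].sum(axis=0)
    for i, ct in enumerate(cell_types):
        indicator = normalize_to_distribution((labels == ct).astype(float))
        for jj in range(len(kept)):
            values[i, jj] = 1.0 - jsd(p_reg[:, jj], indicator)
    return SpecificityMatrix(
        values, cell_types, [activity.regulon_names[j] for j in kept]
    )


def rank_regulons(
    spec: SpecificityMatrix, cell_type: str, top_k: int | None = None
) -> list[tuple[str, float]]:
    """Regulons of one cell type ordered by descending RSS.

    Ties are broken alphabetically by regulon name; a ``top_k`` larger
    than the number of regulons returns the full list.
    """
    if cell_type not in spec.cell_types:
        raise KeyError(f"unknown cell type {cell_type!r}")
    row = spec.values[spec.cell_types.index(cell_type)]
    order = sorted(zip(spec.regulon_names, row), key=lambda t: (-t[1], t[0]))
    if top_k is not None:
        order = order[:top_k]
    return [(name, float(score)) for name, score in order]
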
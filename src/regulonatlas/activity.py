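"""Regulon activity scoring via the area under the recovery curve.

For one observation unit, genes are ranked by decreasing expression and
the recovery curve R(x) counts regulon genes among the top x ranks for
x = 1..k, where k is the top fraction of the gene list (default 5%).
The regulon activity score (RAS) is the area under this step curve
normalized by the maximal achievable area (all regulon genes at the very
top), so a perfectly recovered regulon scores exactly 1 and a regulon
absent from the window scores 0.

Per-regulon activity columns can then be Z-scored across all units and
binarized at Z > 2.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .datatypes import ActivityMatrix, ExpressionMatrix, RegulonSet

logger = logging.getLogger(__name__)

TIE_POLICIES = ("random_within_seed", "average_rank")


@dataclass
class AUCParameters:
    """Recovery-curve window and tie handling.

    top_fraction: fraction of the ranked gene list forming the window;
        the window length is k = max(1, floor(top_fraction * n_genes)).
    tie_policy: ``random_within_seed`` breaks expression ties uniformly
        at random under the seed (the natural choice for sparse counts);
        ``average_rank`` instead scores each tied gene at its expected
        contribution over all tie-breaks, which is seed-free.
    """

    top_fraction: float = 0.05
    tie_policy: str = "random_within_seed"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")

    def window(self, n_genes: int) -> int:
        return max(1, int(np.floor(self.top_fraction * n_genes)))


@dataclass
class BinarizationParameters:
    z_cutoff: float = 2.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_cutoff):
            raise ValueError("z_cutoff must be finite")


def rank_genes(
    row: np.ndarray, tie_policy: str = "random_within_seed", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Order gene indices by decreasing expression.

    With the random tie policy, tied genes are permuted uniformly under
    ``rng`` (a fresh default generator when omitted). With
    ``average_rank`` the returned order uses a stable tie-break; callers
    needing expected-rank semantics should use :func:`score_all`, which
    scores tied genes at their expected recovery contribution.
    """
    row = np.asarray(row, dtype=float)
    if tie_policy == "random_within_seed":
        rng = np.random.default_rng() if rng is None else rng
        shuffle = rng.permutation(row.size)
        return shuffle[np.argsort(-row[shuffle], kind="stable")]
    return np.argsort(-row, kind="stable")


def _max_step_sum(n_regulon_genes: int, k: int) -> float:
    """Area of the best possible recovery curve over a window of k ranks."""
    g = n_regulon_genes
    if g <= k:
        return k * g - g * (g - 1) / 2
    return k * (k + 1) / 2


def compute_auc(
    rank_order: Sequence[int], regulon_indices: Sequence[int], params: AUCParameters
) -> float:
    """Recovery-curve AUC of a regulon in one unit's gene ranking.

    ``rank_order`` is a permutation of gene indices in decreasing
    expression order; ``regulon_indices`` are the regulon's gene indices
    already restricted to genes present in the matrix.
    """
    rank_order = np.asarray(rank_order)
    n_genes = rank_order.size
    g = len(regulon_indices)
    if g == 0:
        logger.warning("regulon has no genes in the matrix; AUC set to 0")
        return 0.0
    k = params.window(n_genes)
    ranks = np.empty(n_genes, dtype=np.int64)
    ranks[rank_order] = np.arange(1, n_genes + 1)
    r = ranks[np.asarray(list(regulon_indices))]
    in_window = r[r <= k]
    return float(np.sum(k - in_window + 1) / _max_step_sum(g, k))


def _expected_contributions(row: np.ndarray, k: int) -> np.ndarray:
    """Per-gene expected step-sum contribution under uniform tie-breaks.

    A gene tied across descending ranks [a, b] contributes the mean of
    (k - r + 1) over r in [a, min(b, k)] weighted by the chance of
    landing there, i.e. divided by the tie-block size.
    """
    lo = scipy.stats.rankdata(-row, method="min")
    hi = scipy.stats.rankdata(-row, method="max")
    m = np.minimum(hi, k)
    width = m - lo + 1
    # arithmetic series sum of (k - r + 1) for r in [lo, m]
    series = (k - lo + 1 + (k - m + 1)) * width / 2.0
    out = np.where(width > 0, series / (hi - lo + 1), 0.0)
    return out


def score_all(
    expr: ExpressionMatrix, regulons: RegulonSet, params: AUCParameters | None = None
) -> ActivityMatrix:
    """Score every regulon in every unit; one rank pass per unit.

    Regulon genes absent from the matrix are dropped with a logged
    count; a regulon with no genes left scores 0 everywhere.
    """
    params = AUCParameters() if params is None else params
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    reg_idx: list[np.ndarray] = []
    for reg in regulons:
        present = sorted(gene_pos[g] for g in reg.genes if g in gene_pos)
        dropped = len(reg.genes) - len(present)
        if dropped:
            logger.info("regulon %s: %d/%d genes absent from matrix",
                        reg.name, dropped, len(reg.genes))
        if not present:
            logger.warning("regulon %s has no genes in the matrix; scores 0", reg.name)
        reg_idx.append(np.asarray(present, dtype=np.int64))
    if all(idx.size == 0 for idx in reg_idx):
        raise ValueError("no regulon has any gene in the matrix")

    n_units, n_genes = expr.values.shape
    k = params.window(n_genes)
    max_sums = np.array([_max_step_sum(idx.size, k) if idx.size else 1.0
                         for idx in reg_idx])
    values = np.zeros((n_units, len(reg_idx)), dtype=float)
    rng = np.random.default_rng(params.seed)
    for u in range(n_units):
        row = expr.values[u]
        if params.tie_policy == "random_within_seed":
            order = rank_genes(row, "random_within_seed", rng)
            ranks = np.empty(n_genes, dtype=np.int64)
            ranks[order] = np.arange(1, n_genes + 1)
            contrib = np.clip(k - ranks + 1, 0, None).astype(float)
        else:
            contrib = _expected_contributions(row, k)
        for j, idx in enumerate(reg_idx):
            if idx.size:
                values[u, j] = contrib[idx].sum() / max_sums[j]
    values = np.clip(values, 0.0, 1.0)
    return ActivityMatrix(values, list(expr.cell_ids), regulons.names, kind="raw_auc")


def binarize(
    activity: ActivityMatrix, params: BinarizationParameters | None = None
) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Z-score each regulon across all units and threshold at Z > cutoff.

    Columns with zero variance produce all-zero Z and binary columns
    (with a warning); the cutoff is a strict inequality.
    """
    params = BinarizationParameters() if params is None else params
    if activity.n_units < 2:
        raise ValueError("binarization needs at least 2 units")
    mean = activity.values.mean(axis=0)
    sd = activity.values.std(axis=0)  # population sd, across all samples
    flat = sd == 0
    if flat.any():
        logger.warning("%d regulon columns have zero variance; binarized to 0",
                       int(flat.sum()))
    safe_sd = np.where(flat, 1.0, sd)
    z = (activity.values - mean) / safe_sd
    z[:, flat] = 0.0
    binary = (z > params.z_cutoff).astype(float)
    zmat = ActivityMatrix(z, list(activity.unit_ids), list(activity.regulon_names),
                          kind="zscore")
    bmat = ActivityMatrix(binary, list(activity.unit_ids),
                          list(activity.regulon_names), kind="binary")
    return zmat, bmat
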
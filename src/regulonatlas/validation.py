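"""Evaluation statistics for the regulon pipeline.

Covers four families of checks: silhouette-based separation of cell
types in activity space (and a one-sided t test comparing two scoring
strategies), Fisher's exact enrichment of cell-type-related entries
among significant top-ranked co-expression datasets, a seeded
permutation null for arbitrary gene-set score functions (1000 draws by
default), and consistency statistics across pooling replicates. The
dataset tables and gene-set score functions are supplied by the caller,
so every statistic is reproducible offline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- silhouette

def silhouette(
    distances: np.ndarray, labels: Sequence[str]
) -> tuple[np.ndarray, pd.Series]:
    """Per-unit silhouette values S_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance from unit i to the other members of its
    label; b_i is the minimum over other labels of the mean distance to
    that label's members. Units in singleton labels get S_i = 0 by
    convention (logged). Returns the per-unit scores and per-label
    means.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray([str(x) for x in labels])
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.min(d) < 0 or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distances must be non-negative, symmetric, zero-diagonal")
    if labels.size != n:
        raise ValueError("one label per unit required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 labels")
    masks = {lab: labels == lab for lab in uniq}
    sizes = {lab: int(m.sum()) for lab, m in masks.items()}
    singletons = [lab for lab, s in sizes.items() if s < 2]
    if singletons:
        logger.info("%d singleton labels score 0 by convention", len(singletons))
    scores = np.zeros(n, dtype=float)
    for i in range(n):
        own = labels[i]
        if sizes[own] < 2:
            continue
        a_i = d[i, masks[own]].sum() / (sizes[own] - 1)
        b_i = min(d[i, masks[lab]].mean() for lab in uniq if lab != own)
        denom = max(a_i, b_i)
        scores[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    means = pd.Series(
        {lab: float(scores[masks[lab]].mean()) for lab in uniq}, name="silhouette"
    )
    return scores, means


def compare_silhouettes(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """One-sided two-sample t test of mean(a) > mean(b).

    Side a is the pooled-scoring (Avg20) condition; returns
    (t statistic, one-sided p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per side")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate: zero variance on both sides")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(t), float(p)


# ------------------------------------------------------- dataset enrichment

def top_rank_enrichment(
    table: pd.DataFrame, p_cutoff: float = 0.01
) -> float:
    """Fisher enrichment of related entries among significant datasets.

    ``table`` has one row per co-expression dataset with columns
    ``rank`` (unique 1..n), ``p_value`` and ``related`` (boolean flag
    for the queried cell type's keywords). Datasets with p < cutoff are
    "significant"; the one-sided hypergeometric tail tests whether
    related datasets are over-represented among them.
    """
    required = {"rank", "p_value", "related"}
    if not required.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if len(table) == 0:
        raise ValueError("empty dataset table")
    ranks = table["rank"].to_numpy()
    if len(np.unique(ranks)) != len(ranks):
        raise ValueError("dataset ranks must be unique")
    p = table["p_value"].to_numpy(dtype=float)
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    related = table["related"].to_numpy(dtype=bool)
    if related.all() or not related.any():
        raise ValueError("need at least one related and one unrelated dataset")
    sig = p < p_cutoff
    contingency = [
        [int((sig & related).sum()), int((sig & ~related).sum())],
        [int((~sig & related).sum()), int((~sig & ~related).sum())],
    ]
    return float(scipy.stats.fisher_exact(contingency, alternative="greater")[1])


def match_keywords(titles: Sequence[str], keywords: Sequence[str]) -> np.ndarray:
    """Case-insensitive substring match of any keyword per title."""
    lowered = [k.lower() for k in keywords]
    return np.array([any(k in str(t).lower() for k in lowered) for t in titles])


# ------------------------------------------------------- permutation null

@dataclass
class PermutationResult:
    observed_score: float
    null_scores: np.ndarray
    n_permutations: int
    seed: int

    @property
    def p_value(self) -> float:
        """#{null > observed} / n, with a strict inequality."""
        return float(np.sum(self.null_scores > self.observed_score)
                     / self.n_permutations)

    def formatted(self) -> str:
        if self.p_value == 0:
            return f"p < {1 / self.n_permutations:g}"
        return f"p = {self.p_value:g}"


def permutation_pvalue(
    score_function: Callable[[Sequence[str]], float],
    gene_set: Sequence[str],
    gene_universe: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for a gene-set score.

    Draws ``n_permutations`` gene sets of the same size as the input,
    without replacement from the universe, scores each, and counts how
    often the random score strictly exceeds the observed one.
    """
    gene_set = list(gene_set)
    universe = np.asarray(list(gene_universe))
    if len(gene_set) >= universe.size:
        raise ValueError("gene universe must be strictly larger than the gene set")
    observed = float(score_function(gene_set))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=float)
    for i in range(n_permutations):
        draw = rng.choice(universe, size=len(gene_set), replace=False)
        try:
            null[i] = float(score_function(list(draw)))
        except Exception as exc:
            raise RuntimeError(
                f"score function failed on permutation {i}: {exc}"
            ) from exc
    return PermutationResult(observed, null, n_permutations, seed)


# ------------------------------------------------- replicate consistency

def replicate_regulon_overlap(
    tf_sets_by_replicate: Mapping[str, set[str]], universe_size: int
) -> pd.DataFrame:
    """Pairwise TF-set overlap across replicates with one-sided Fisher p.

    The 2x2 margins need an explicit TF universe size (membership in
    set A x membership in set B over the universe).
    """
    if universe_size is None:
        raise ValueError("an explicit TF universe size is required")
    reps = list(tf_sets_by_replicate)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    union = set().union(*tf_sets_by_replicate.values())
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of TF sets")
    rows = []
    for ra, rb in itertools.combinations(reps, 2):
        a, b = tf_sets_by_replicate[ra], tf_sets_by_replicate[rb]
        ov = len(a & b)
        contingency = [
            [ov, len(a) - ov],
            [len(b) - ov, universe_size - len(a) - len(b) + ov],
        ]
        p = float(scipy.stats.fisher_exact(contingency, alternative="greater")[1])
        rows.append((ra, rb, ov, p))
    return pd.DataFrame(rows, columns=["replicate_a", "replicate_b",
                                       "overlap", "fisher_p"])


def replicate_ras_agreement(
    distance_matrices: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Pairwise Pearson correlation of vectorized distance matrices.

    Each replicate supplies a square distance matrix over the same
    units (in the same order); agreement is the PCC of the strict
    upper triangles.
    """
    reps = list(distance_matrices)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    shapes = {np.asarray(distance_matrices[r]).shape for r in reps}
    if len(shapes) != 1:
        raise ValueError("distance matrices differ in shape")
    n = next(iter(shapes))[0]
    iu = np.triu_indices(n, k=1)
    rows = []
    for ra, rb in itertools.combinations(reps, 2):
        va = np.asarray(distance_matrices[ra], dtype=float)[iu]
        vb = np.asarray(distance_matrices[rb], dtype=float)[iu]
        rows.append((ra, rb, float(np.corrcoef(va, vb)[0, 1])))
    return pd.DataFrame(rows, columns=["replicate_a", "replicate_b", "pcc"])
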
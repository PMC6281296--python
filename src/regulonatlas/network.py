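"""Cell-type relatedness network and Markov clustering.

Cell types with similar overall regulon activity share regulatory
programs. Each cell type is summarized by its mean activity profile
over regulons; a pair of cell types is connected when the Spearman
correlation of their profiles exceeds 0.8 (strict). The resulting
graph is partitioned with the Markov Clustering Algorithm (MCL):
alternating expansion (squaring the column-stochastic transition
matrix) and inflation (elementwise power, default 2, followed by
column renormalization) until the flow matrix converges to attractors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import ActivityMatrix, CellAnnotation

logger = logging.getLogger(__name__)


@dataclass
class CellTypeNetwork:
    """Undirected cell-type graph; every edge has rho > threshold."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float = 0.8

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="rho")
        return g


@dataclass
class MCLParameters:
    inflation: float = 2.0
    expansion: int = 2
    pruning_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tolerance: float = 1e-8
    check_stochastic: bool = False

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


def celltype_activity_profiles(
    activity: ActivityMatrix,
    annotation: CellAnnotation,
    celltype_label_field: str = "cell_type",
) -> ActivityMatrix:
    """Per-cell-type mean activity (cell types x regulons)."""
    labels = annotation.labels_for(activity.unit_ids, celltype_label_field)
    frame = pd.DataFrame(activity.values, columns=activity.regulon_names)
    means = frame.groupby(pd.Series(labels, name=celltype_label_field)).mean()
    means = means.sort_index()
    return ActivityMatrix(
        means.to_numpy(),
        [str(i) for i in means.index],
        list(activity.regulon_names),
        kind="celltype_mean",
    )


def build_network(
    profiles: ActivityMatrix, threshold: float = 0.8
) -> CellTypeNetwork:
    """Connect cell types whose profile Spearman rho strictly exceeds threshold."""
    if profiles.n_units < 2:
        raise ValueError("network needs at least 2 cell types")
    if profiles.values.shape[1] < 3:
        raise ValueError("network needs at least 3 regulons")
    nodes = list(profiles.unit_ids)
    ok = np.ptp(profiles.values, axis=1) > 0
    for i in np.where(~ok)[0]:
        logger.warning("cell type %s has a constant profile; left isolated",
                       nodes[i])
    # Spearman = Pearson on ranks; computed only over non-constant profiles
    ranks = scipy.stats.rankdata(profiles.values[ok], axis=1)
    rho_ok = np.atleast_2d(np.corrcoef(ranks))
    keep_idx = np.where(ok)[0]
    edges: list[tuple[str, str, float]] = []
    for a in range(len(keep_idx)):
        for b in range(a + 1, len(keep_idx)):
            r = rho_ok[a, b]
            if np.isfinite(r) and r > threshold:
                i, j = keep_idx[a], keep_idx[b]
                edges.append((nodes[i], nodes[j], float(r)))
    return CellTypeNetwork(nodes=nodes, edges=edges, threshold=threshold)


def _mcl_matrix(
    adj: np.ndarray, params: MCLParameters
) -> np.ndarray:
    """Run MCL flow iterations on an adjacency matrix with self-loops added."""
    n = adj.shape[0]
    m = adj.astype(float).copy()
    np.fill_diagonal(m, 1.0)  # self-loops stabilize the flow
    m /= m.sum(axis=0, keepdims=True)
    for iteration in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.pruning_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0
        if dead.any():  # pruned-away column: park the walker on itself
            m[np.where(dead)[0], dead] = 1.0
            colsum = m.sum(axis=0, keepdims=True)
        m /= colsum
        if params.check_stochastic:
            assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)
        if np.max(np.abs(m - prev)) < params.convergence_tolerance:
            return m
    residual = float(np.max(np.abs(m - prev)))
    raise RuntimeError(
        f"MCL did not converge in {params.max_iterations} iterations "
        f"(residual {residual:.2e})"
    )


def mcl_cluster(
    network: CellTypeNetwork,
    params: MCLParameters | None = None,
    weighted: bool = False,
) -> dict[str, str]:
    """Partition the network with MCL; returns node -> group label.

    Clusters are read from the attractor structure of the converged
    flow matrix (rows with positive diagonal mass; overlapping
    attractor systems merged). Nodes attracted to no attractor join the
    cluster of their strongest neighbor. Groups are labelled G1, G2, ...
    by decreasing size, ties broken by lexicographic smallest member.
    """
    params = MCLParameters() if params is None else params
    nodes = list(network.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    pos = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=float)
    for a, b, rho in network.edges:
        w = rho if weighted else 1.0
        adj[pos[a], pos[b]] = adj[pos[b], pos[a]] = w
    m = _mcl_matrix(adj, params)

    eps = params.pruning_threshold
    attractors = [i for i in range(n) if m[i, i] > eps]
    overlap = nx.Graph()
    overlap.add_nodes_from(attractors)
    member_of: dict[int, list[int]] = {i: [] for i in range(n)}
    for a in attractors:
        for j in np.where(m[a] > eps)[0]:
            member_of[j].append(a)
    for j, atts in member_of.items():
        for a, b in zip(atts, atts[1:]):
            overlap.add_edge(a, b)
    comp_of_attractor: dict[int, int] = {}
    n_comps = 0
    for comp in nx.connected_components(overlap):
        for a in comp:
            comp_of_attractor[a] = n_comps
        n_comps += 1
    cluster_of: dict[int, int] = {}
    for j in range(n):
        if member_of[j]:
            cluster_of[j] = comp_of_attractor[member_of[j][0]]
    next_id = n_comps
    for j in range(n):
        if j in cluster_of:
            continue
        neighbors = np.where(adj[j] > 0)[0]
        assigned = [(adj[j, v], nodes[v], v) for v in neighbors if v in cluster_of]
        if assigned:
            _, _, best = max(assigned, key=lambda t: (t[0], t[1]))
            cluster_of[j] = cluster_of[best]
        else:
            cluster_of[j] = next_id
            next_id += 1

    groups: dict[int, list[str]] = {}
    for j, c in cluster_of.items():
        groups.setdefault(c, []).append(nodes[j])
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    out: dict[str, str] = {}
    for rank, members in enumerate(ordered, start=1):
        for v in members:
            out[v] = f"G{rank}"
    return out


def group_module_crosstab(
    groups: dict[str, str], module_activity_by_celltype: pd.DataFrame
) -> pd.DataFrame:
    """Groups x modules table of mean module activity over group members.

    ``module_activity_by_celltype`` is modules x cell types (as produced
    by :func:`regulonatlas.modules.module_activity_table`).
    """
    table_types = set(map(str, module_activity_by_celltype.columns))
    group_types = set(groups)
    if table_types != group_types:
        raise ValueError(
            "cell-type coverage mismatch between groups and module activity "
            f"(only in groups: {sorted(group_types - table_types)[:3]}, "
            f"only in table: {sorted(table_types - group_types)[:3]})"
        )
    group_labels = sorted(set(groups.values()), key=lambda g: (len(g), g))
    out = pd.DataFrame(index=group_labels,
                       columns=list(module_activity_by_celltype.index), dtype=float)
    for g in group_labels:
        members = [ct for ct, lab in groups.items() if lab == g]
        out.loc[g] = module_activity_by_celltype[members].mean(axis=1)
    return out


def write_edge_list(network: CellTypeNetwork, path) -> None:
    pd.DataFrame(network.edges, columns=["cell_type_a", "cell_type_b", "rho"]).to_csv(
        path, sep="\t", index=False
    )
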
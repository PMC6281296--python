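"""Synthetic atlas generator with planted ground truth.

Emulates the structure of a multi-tissue single-cell atlas: cells
stratified by (tissue, cell type), non-negative counts with
overdispersion and dropout, and regulons whose TF and targets are
co-elevated in specific cell types. Counts follow a negative binomial
(the standard scRNA-seq stand-in; dispersion exposed) around per-gene
baseline means drawn from a Gamma distribution, multiplied by the
effect size for genes of regulons active in the cell's (type, tissue),
then thinned by independent Bernoulli dropout.

Cell types are organized into families that share regulon modules:
regulons of one module are active across the module's whole cell-type
family, with full effect in each regulon's own primary cell type and an
intermediate effect in the other family members. This plants, at once,
recoverable structure for activity scoring (elevated regulon genes),
specificity (a unique argmax cell type per regulon), CSI modules
(co-active regulon groups) and the cell-type network (correlated
within-family activity profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, ExpressionMatrix, Regulon, RegulonSet


def _even_partition(items: list, n_parts: int) -> list[list]:
    sizes = [len(items) // n_parts + (1 if i < len(items) % n_parts else 0)
             for i in range(n_parts)]
    out, start = [], 0
    for s in sizes:
        out.append(items[start : start + s])
        start += s
    return out


@dataclass
class SyntheticSpec:
    """Parameters of the planted-atlas model (defaults = benchmark)."""

    n_cell_types: int = 5
    n_tissues: int = 2
    cells_per_type: int = 50  # per tissue
    n_genes: int = 2000
    n_regulons: int = 12
    targets_per_regulon: int = 50
    n_modules: int = 3
    effect_size: float = 4.0
    baseline_mean: float = 1.0
    dispersion: float = 0.5  # NB variance = mu + dispersion * mu^2
    dropout_rate: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_regulons * (self.targets_per_regulon + 1) > self.n_genes:
            raise ValueError(
                "infeasible: regulon genes "
                f"({self.n_regulons} x {self.targets_per_regulon + 1}) exceed "
                f"n_genes ({self.n_genes})"
            )
        if not 1 <= self.n_modules <= self.n_regulons:
            raise ValueError("n_modules must lie in [1, n_regulons]")

    @property
    def secondary_effect(self) -> float:
        """Fold-elevation in non-primary family members (midway to baseline)."""
        return 1.0 + (self.effect_size - 1.0) / 2.0


@dataclass
class GroundTruth:
    """The planted structure a recovery test checks against."""

    regulon_targets: dict[str, list[str]]
    activity_map: dict[str, set[tuple[str, str]]]  # regulon -> {(cell_type, tissue)}
    primary_celltype: dict[str, str]
    module_of: dict[str, str]
    celltype_families: list[list[str]]

    def family_of(self) -> dict[str, str]:
        return {ct: f"F{i + 1}" for i, fam in enumerate(self.celltype_families)
                for ct in fam}


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, CellAnnotation, RegulonSet, GroundTruth]:
    """Draw one atlas realization; byte-identical for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    cell_types = [f"ct{i + 1}" for i in range(spec.n_cell_types)]
    tissues = [f"tissue{i + 1}" for i in range(spec.n_tissues)]
    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]

    families = _even_partition(cell_types, spec.n_modules)
    reg_names = [f"Reg{i + 1:02d}" for i in range(spec.n_regulons)]
    module_groups = _even_partition(reg_names, spec.n_modules)

    block = spec.targets_per_regulon + 1
    regulons, truth_targets = [], {}
    activity_map: dict[str, set[tuple[str, str]]] = {}
    primary: dict[str, str] = {}
    module_of: dict[str, str] = {}
    for m_idx, members in enumerate(module_groups):
        family = families[m_idx]
        for r_idx, name in enumerate(members):
            g0 = reg_names.index(name) * block
            tf = gene_ids[g0]
            targets = gene_ids[g0 + 1 : g0 + block]
            regulons.append(Regulon(name=name, tf=tf, targets=frozenset(targets)))
            truth_targets[name] = targets
            primary[name] = family[r_idx % len(family)]
            activity_map[name] = {(ct, ti) for ct in family for ti in tissues}
            module_of[name] = f"M{m_idx + 1}"
    regulon_set = RegulonSet(regulons)

    gene_means = rng.gamma(shape=2.0, scale=spec.baseline_mean / 2.0,
                           size=spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    r_nb = 1.0 / spec.dispersion

    blocks, cell_rows = [], []
    cell_counter = 0
    for tissue in tissues:
        for ct in cell_types:
            mult = np.ones(spec.n_genes)
            for reg in regulon_set:
                if (ct, tissue) in activity_map[reg.name]:
                    e = (spec.effect_size if primary[reg.name] == ct
                         else spec.secondary_effect)
                    idx = [gene_pos[g] for g in reg.genes]
                    mult[idx] = e
            mu = gene_means * mult
            p_nb = r_nb / (r_nb + mu)
            counts = rng.negative_binomial(
                r_nb, p_nb, size=(spec.cells_per_type, spec.n_genes)
            ).astype(float)
            if spec.dropout_rate > 0:
                keep = rng.random(counts.shape) >= spec.dropout_rate
                counts *= keep
            blocks.append(counts)
            for _ in range(spec.cells_per_type):
                cell_counter += 1
                cell_rows.append(
                    (f"c{cell_counter:05d}", tissue, ct, f"{tissue}.{ct}")
                )
    values = np.vstack(blocks)
    cell_ids = [r[0] for r in cell_rows]
    expr = ExpressionMatrix(values, cell_ids, gene_ids)
    annotation = CellAnnotation(
        pd.DataFrame(cell_rows, columns=["cell_id", "tissue", "cell_type", "cluster"])
    )
    truth = GroundTruth(
        regulon_targets=truth_targets,
        activity_map=activity_map,
        primary_celltype=primary,
        module_of=module_of,
        celltype_families=families,
    )
    return expr, annotation, regulon_set, truth


def default_benchmark(
    seed: int = 7,
) -> tuple[ExpressionMatrix, CellAnnotation, RegulonSet, GroundTruth]:
    """The standard recovery fixture: 500 cells x 2,000 genes.

    5 cell types x 2 tissues x 50 cells, 12 planted regulons of 50
    targets each in 3 modules, effect size 4, dropout 0.3, seed 7.
    """
    return generate(SyntheticSpec(seed=seed))
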
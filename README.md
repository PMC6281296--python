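# regulonatlas

Regulon-centric analysis of single-cell atlases: pseudocell pooling,
regulon activity scoring, cell-type specificity, combinatorial regulon
modules, and cell-type relatedness networks — with a synthetic
generator that plants recoverable ground truth, so every stage has an
offline benchmark.

## The problem

A transcription factor (TF) and its direct target genes form a
*regulon*, the working unit of a gene regulatory network. Given a
cells × genes expression matrix, per-cell annotations (tissue, cell
type) and regulon definitions, this package answers three questions a
single-cell atlas raises:

1. **How active is each regulon in each cell?** The regulon activity
   score (RAS) is the area under the recovery curve of the regulon's
   genes within the top 5% of that cell's expression ranking,
   normalized so a perfectly recovered regulon scores 1. Activity can
   be Z-scored across all cells and binarized at Z > 2.5.
2. **Which regulons define a cell type?** The regulon specificity
   score compares the regulon's normalized activity distribution P_R
   over cells against the normalized indicator P_C of a cell type via
   the Jensen–Shannon divergence (base-2 entropy, so JSD ∈ [0, 1]):

       RSS(R, C) = 1 − JSD(P_R, P_C)

   Regulons ranked by RSS within a cell type nominate its candidate
   critical regulators.
3. **How do regulons and cell types organize globally?** Pairwise
   Pearson correlation of RAS is sharpened into the Connection
   Specificity Index — CSI(A, B) is the fraction of other regulons
   whose correlation with both A and B is below corr(A, B) — and
   hierarchically clustered into regulon modules (CSI > 0.7 defines
   the regulon association network). Cell types whose mean activity
   profiles have Spearman ρ > 0.8 are connected and partitioned with
   the Markov Clustering Algorithm (inflation 2).

Noisy single-cell profiles can be stabilized first by *Avg20 pooling*:
averaging random, non-overlapping groups of 20 cells within each
(tissue, cell type) stratum into pseudocells, repeated across three
seeded replicates whose agreement is checked statistically. Evaluation
statistics (silhouette separation, Fisher-exact enrichment of ranked
dataset tables, permutation nulls for gene-set scores) live in
`regulonatlas.validation`.

## Worked example

```python
from regulonatlas.synthetic import default_benchmark
from regulonatlas.activity import AUCParameters, score_all
from regulonatlas.specificity import rss, rank_regulons

expr, annotation, regulons, truth = default_benchmark()   # 500 cells x 2,000 genes
ras = score_all(expr, regulons, AUCParameters(seed=1))    # cells x 12 regulons
spec = rss(ras, annotation)                               # 5 cell types x 12 regulons
for name, score in rank_regulons(spec, "ct1", top_k=3):
    print(f"{name}\t{score:.3f}")
```

prints

```
Reg01	0.742
Reg03	0.740
Reg04	0.516
```

`Reg01` and `Reg03` are the two regulons planted with full effect in
cell type `ct1` (`truth.primary_celltype["Reg01"] == "ct1"`), so they
top the ranking; `Reg04` belongs to the same planted module and is
secondarily active in `ct1`, and every other regulon scores far lower.
An RSS of 0.74 means the regulon's activity distribution over the 500
cells is close to (but, because of background activity and dropout,
not identical to) the uniform indicator of the 100 `ct1` cells.

The same pipeline runs from the shell:

```sh
regulon-atlas synth --seed 7 --out data/
regulon-atlas run-all --matrix data/matrix.mtx --genes data/genes.txt \
    --cells data/cells.txt --annotation data/annotation.tsv \
    --regulons data/regulons.gmt --n-modules 3 --seed 0 --out results/
```

which writes pooled matrices (3 replicates), RAS (raw / Z / binary),
RSS with per-cell-type rankings, the CSI matrix with modules and the
regulon association network, the cell-type network with MCL groups,
the replicate-agreement report, and a provenance JSON recording every
parameter and derived seed.

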
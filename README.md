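# scproprio

Iterative, bootstrapped clustering and marker analysis for plate-based
single-cell RNA-seq of proprioceptive sensory neurons — the dorsal root
ganglion neurons that innervate muscle spindles and Golgi tendon organs.
Because the transcriptional differences between proprioceptor subtypes
are subtle compared with the differences between major DRG classes, the
workflow is built around high-depth UMI counts, careful removal of
satellite-glia-contaminated captures, and a conservative
cluster-discovery loop whose robustness is established by bootstrap
co-clustering rather than by a single partition.

The package is for computational biologists who want to run, test, or
extend this analysis. Every stage is a library function; numbered
drivers under `analysis/` run the study end to end on a bundled
synthetic-data generator with full planted ground truth, so every claim
the pipeline makes is checkable without downloading anything.

## The method

Starting from a genes × cells UMI count matrix:

1. **QC.** Cells detecting fewer than 2000 genes are removed, then cells
   with satellite-cell contamination: either *Mbp* CPM ≥ 10,000 or
   *Apoe* CPM ≥ 20 (default dialect), or summed *Apoe*+*Mpz* counts above
   10% of the dataset mean (alternative dialect). CPM is
   count / cell total × 10⁶.
2. **Gene modules.** On the cells in scope, the top 6000 genes by Fano
   factor (variance/mean of CPM) enter a WGCNA-style co-expression
   network: adjacency a₍ᵢⱼ₎ = |r₍ᵢⱼ₎|^β on log₁₀(CPM+1) with soft power
   β = 1, average-linkage clustering of d = 1 − a (cut ceiling 0.995),
   coherent detached branches become candidate modules, and each module
   must beat a gene-permutation null for mean within-module |r| on
   held-out cells (modules are detected on ⅔ of the cells and validated
   on the remaining ⅓).
3. **Cell splitting.** Each module is summarized by its eigengene (first
   PC of the z-scored module submatrix); cells are clustered by Ward
   linkage on 1 − r between their eigengene vectors.
4. **Merging.** For every candidate cluster pair, a moderated t-test
   (log₂(CPM+1), gene variances shrunk toward the median with d₀ = 4
   prior df) defines DE genes (BH-adjusted p < 0.05, |log₂FC| ≥ 1);
   the pair's distinctness score is Σ min(−log₁₀ p, 20) over DE genes,
   and pairs scoring below 100 are merged. The procedure recurses into
   each surviving cluster until no significant modules remain.
5. **Consensus.** Steps 1–4 are repeated on random 80% cell subsets
   (default 100 runs); the co-clustering matrix records, for each cell
   pair, the fraction of co-sampled runs in which they landed together,
   and reference clusters with mean cross co-clustering > 0.25 merge.
   Final clusters under 15 cells are flagged as minor.
6. **Markers, enrichment, embedding, lineage.** Markers are genes DE in
   ≥ 2 cluster pairs with binary on/off expression (detected in ≥ 70% of
   one cluster's cells, ≤ 20% of another's). Gene-set enrichment offers
   the classic one-sided Fisher/hypergeometric test and the elim
   variant, which removes a significant child set's study genes from its
   ancestors before testing them. Cells are embedded by t-SNE on the top
   20 PCs of log₁₀(CPM+1) over all DE genes. The lineage panel computes
   gene–gene Pearson correlations of log(CPM+1) per developmental stage,
   displayed in the gene order of the adult stage's average-linkage
   clustering.

## Worked example

```bash
python analysis/01_simulate_data.py      # writes results/data/
python analysis/02_qc_filter.py
python analysis/03_iterative_clustering.py
python analysis/04_consensus.py
python analysis/05_markers_de.py
python analysis/06_enrichment.py
python analysis/07_lineage_correlations.py
```

Output of the run above (seed 0):

```
benchmark: 2500 genes x 184 cells (10 low-depth, 8 contaminated) -> results/data/benchmark
kept 166/184 cells; removed 10 low-depth (exact: True), 8 contaminated (exact: True) [dialect: methods]
5 clusters (5 major): {'c1': 51, 'c2': 31, 'c3': 28, 'c4': 28, 'c5': 28}; ARI vs planted = 1.000
25 bootstrap runs; 0 consensus merge(s); final 5 clusters {...}; ARI vs planted = 1.000
10 cluster pairs tested; 100 markers selected (precision 1.00, recall 1.00); embedding on 20 PCs
5/12 sets pass all filters: ['module_cluster1', ..., 'module_cluster5']
mean within-module |r| by stage: 0.372 (e14) < 0.595 (p0) < 0.715 (p12) < 0.903 (adult)
```

Reading this: QC removed exactly the planted low-depth and contaminated
cells; the pipeline recovered the five planted subtypes at their exact
sizes (51/31/28/28/28 of 166 cells) with adjusted Rand index 1.0 against
the planted labels; bootstrap consensus confirmed the partition (no
pair of clusters co-clustered above 0.25); all 100 planted markers were
selected with no false positives; enrichment flagged exactly the five
planted marker modules and none of the background sets; and marker
co-expression strengthens monotonically toward the mature stage, as the
time-course design plants.

The same stages are available as a CLI (`scproprio simulate|qc|cluster|
consensus|markers|enrich|lineage|embed|run-all`) and as library calls —
see `scproprio.run_pipeline`.

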
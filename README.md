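# ciliamod

In-silico dissection of ciliated-cell transcriptomes from bulk expression
data, by weighted gene coexpression network meta-analysis.

## The problem

Bulk tissue samples are mixtures of cell types, and the proportion of each
cell type varies from sample to sample. Genes transcribed specifically in
one cell type therefore rise and fall together across samples, forming a
coexpression module whose shared driver is the latent cell-type fraction.
`ciliamod` exploits this to characterize cells carrying motile cilia —
ependymal cells in brain ventricles, airway epithelium, fallopian-tube and
endometrial epithelium — from ordinary bulk microarray or RNA-seq panels,
without sorting or single-cell data. It is aimed at computational
biologists studying cilia and ciliopathies who want a reproducible,
testable implementation of the full analysis chain.

## The method

Per dataset (WGCNA-style):

1. **Network** — Pearson correlations r_ij for all gene pairs on a random
   seed set (default 4,000 genes); unsigned soft-threshold adjacency
   a_ij = |r_ij|^β with β chosen per network by the scale-free topology
   criterion (smallest β with signed R² ≥ 0.8, subject to mean
   connectivity ≥ 1); topological overlap
   TO_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
   ℓ_ij = Σ_u a_iu a_uj.
2. **Modules** — average-linkage clustering of 1 − TO, adaptive dendrogram
   cut (minimum module size 10, deep-split enabled).
3. **Genome-scale expansion** — each module is summarized by a module
   eigengene (ME): the standardized mean of the z-scored profiles of its
   10 most intramodularly connected genes. Module membership
   MM_gm = cor(x_g, ME_m) assigns every measured gene to its argmax-MM
   module when max MM ≥ 0.5, else to none.
4. **Ciliary module** — the module most enriched in golden-standard ciliary
   markers (one-sided Fisher's exact test, P < 10⁻³).

Across datasets:

5. **Consensus signature** — genes in the ciliary module in ≥ 2 of 3
   tissues and ≥ 4 of 10 datasets; FDR by size-preserving random module
   replacement (1,000 iterations), FDR = mean permuted signature size /
   observed size.
6. **Novelty** — genes stratified by prior study evidence: I (high
   confidence ≥ 1 study or medium ≥ 2), II (medium = 1 or any low), III
   (none).
7. **Tissue specificity** — body-atlas expression Z-scored per gene;
   tissues ranked by mean signature Z; per gene, a mean-rank permutation
   test of up-regulation in ciliated tissues (brain excluded), BH
   corrected.
8. **Differential coexpression** — hubs (module member with
   MM_ciliary ≥ 0.75) restricted to one tissue (> ½ of its datasets, member
   nowhere else) are tested by one-way ANOVA on Fisher-transformed MM and
   validated by t-tests in the atlas.

A synthetic-data module generates expression collections, marker sets,
evidence tables and a body atlas with known planted structure, so every
stage is testable end to end without external data.

## Worked example

```sh
ciliamod simulate --seed 4 --out sim/       # synthetic collection + atlas
ciliamod run-all --config sim/pipeline.yaml --out results/
```

or, in Python, on the default synthetic design (10 datasets, 3 tissues,
2,000 genes × 60 samples, a planted 150-gene ciliary signature with 25
markers):

```python
from ciliamod import GeneratorConfig, PipelineConfig
from ciliamod.pipeline import run_collection, simulate_inputs

datasets, markers, evidence, atlas, truth = simulate_inputs(GeneratorConfig(seed=7))
report = run_collection(datasets, markers, evidence, atlas,
                        PipelineConfig(seed=7, n_permutations=10**4))
print(report.per_dataset[["dataset_id", "n_modules", "ciliary_size",
                          "enrichment_p"]].head(3))
print(len(report.signature.genes), report.signature.fdr)
```

prints

```
  dataset_id  n_modules  ciliary_size  enrichment_p
0    brain_0          4           126  2.026092e-21
1    brain_1          4           134  7.286980e-25
2    brain_2          4           134  5.742008e-24
```

followed by `150 0.0378...`: in each dataset four modules are found, the
marker-enriched one holds ~130 genes (the planted 150 minus dropouts and
weak-loading members, recaptured at consensus), the enrichment p-values are
far below 10⁻³, and the consensus signature recovers all 150 planted genes
at an estimated FDR of ~3.8%. The report also carries the tissue ranking
(all six ciliated atlas tissues on top), per-gene specificity p-values, and
the differential-coexpression table with the planted tissue-restricted
hubs.

The per-dataset stages are scikit-learn-style estimators and compose with
sklearn tooling:

```python
from ciliamod import CoexpressionModules, GenomeScaleExpander
net = CoexpressionModules(min_module_size=10).fit(datasets[0])   # genes x samples
exp = GenomeScaleExpander(power=net.power_).fit(datasets[0].expr, net.labels_)
mm = exp.transform(datasets[0].expr)                              # gene x module kME
```

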
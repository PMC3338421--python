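# Methods

## Model and assumptions

The analysis rests on one assumption: in a bulk tissue sample, the
expression of a gene transcribed specifically in ciliated cells is, on a
log scale, approximately linear in the (log-ish) abundance of those cells.
When the ciliated-cell fraction varies across samples, all such genes
covary, and the coexpression module they form can be isolated without any
cell sorting. Everything downstream — eigengene summarization, membership
expansion, cross-dataset consensus — is machinery for finding that module
robustly and separating it from modules driven by other latent factors
(other cell types, proliferation, immune infiltration).

The method assumes expression matrices are already normalized, complete
(no missing entries) and log-scale; genes with zero variance are dropped
with a warning at ingestion. Within a dataset no batch structure is
modeled. Datasets are treated as exchangeable replicates within their
tissue.

## Per-dataset network analysis

**Seed set.** Networks are built on a uniform random subset of genes
(default 4,000; the whole gene set when smaller) to bound the O(n²)–O(n³)
cost; the expansion step restores genome scale.

**Soft power.** Unsigned adjacency a_ij = |r_ij|^β. β is the smallest
candidate (1–20) whose signed scale-free fit R² reaches 0.8, where the fit
regresses log10(frequency) on log10(mean connectivity) over 10 equal-width
connectivity bins (empty bins dropped, ≥ 3 required) and the R² is signed
by −sign(slope) so increasing degree distributions are penalized. Two
guards: if no candidate reaches the threshold, the maximizer is used; and
candidates leaving mean connectivity below 1 are excluded (unless all
would be), because at such powers the adjacency is numerically empty and
an apparently excellent scale-free fit reflects noise — on small gene sets
this otherwise selects powers that destroy module structure.

**Topological overlap.** TO_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
with ℓ_ij = Σ_{u≠i,j} a_iu a_uj. The adjacency diagonal is excluded from
k_i and ℓ_ij; the TOM diagonal is 1 by convention. The matrix is
symmetrized and clipped to [0, 1] against floating-point drift.

**Clustering and module detection.** 1 − TO is clustered by average
linkage (scipy). The dendrogram is cut adaptively in two stages:

1. a static cut at 95% of the root height separates tight branches from
   the high-merging agglomerate of mutually uncorrelated genes; components
   of ≥ `min_size` (default 10) leaves become candidate modules, smaller
   ones are unassigned. If nothing qualifies, the tree carries no height
   structure and all leaves form a single module — a flat dendrogram is
   evidence for one cluster, not none.
2. with `deep_split` (default on), each candidate subtree is decomposed
   recursively: a merge is a module boundary when both branches hold
   ≥ `min_size` leaves and both are *distinct*, i.e. their core tops sit
   more than 10% of the root height below the joining height. A branch's
   core top is its highest merge joining two sub-branches of ≥ `min_size`
   leaves each (straggler attachments stripped); a branch with no such
   merge is measured by its own top merge. Straggler chains (< `min_size`
   leaves) attaching to an undivided branch are absorbed into it;
   stragglers above a divided branch stay unassigned.

Disabling `deep_split` skips stage 2, so enabling it can only refine the
partition. Module ids are assigned by decreasing size (ties by smallest
leaf index), making the whole pipeline deterministic. This is an original
dendrogram-based adaptive-cut design; its contract is recovery of planted
structure (tested), not label-level equality with any particular cutting
implementation. Known behavior: at low powers a detected module can absorb
a few chained noise genes; these have low membership and are shed at the
expansion stage, which is why genome-scale agreement with planted
structure (ARI ≥ 0.9) is asserted after expansion while the raw cut is
held to a looser standard.

## Eigengenes and genome-scale expansion

A module eigengene is the mean of the z-scored profiles of the module's 10
most intramodularly connected genes (all genes if fewer), re-standardized
to mean 0, SD 1. Standardizing *before* averaging makes the summary
scale-free and order-free; the order of operations is fixed and kept
consistent everywhere. The ME sign is fixed so hub genes correlate
positively with it on average. Connectivity ties at the 10th rank are
broken by gene id and logged.

Module membership (kME) is the Pearson correlation of any gene's profile
with an ME. Genes are assigned to their argmax-MM module when max MM ≥ 0.5
(ties to the lower module id), else left unassigned. Expansion is
idempotent: re-applying the assignment to its own output changes nothing.

## Ciliary-module identification and consensus

Marker enrichment is the one-sided hypergeometric upper tail
P(X ≥ overlap); the enrichment universe is the dataset's own measured gene
set after filtering (the least-biased choice when platforms differ), and
cross-dataset module overlaps use the intersection of the two universes.
The winning module must reach P < 10⁻³; ties go to the larger marker
overlap, then the lower module id. Datasets without a qualifying module
are reported and excluded from the consensus, not fatal.

The consensus keeps genes in the ciliary module in ≥ 2 tissues and ≥ 4
datasets simultaneously, counting only datasets where the gene is measured
(thresholds unchanged for partially measured genes). The permutation FDR
redraws each dataset's ciliary module uniformly from that dataset's
available universe — size preserved, availability masks respected so a
gene absent from a platform is never drawn there — rebuilds the consensus,
and reports mean permuted size / observed size over 1,000 seeded
iterations (NA with a warning if the observed signature is empty).

Novelty stratification: category I if high-confidence evidence in ≥ 1
study or medium in ≥ 2; II if medium in exactly 1 or any low-confidence
evidence; III otherwise. Genes missing from the evidence table count as
zero evidence (logged). Percentages in summary tables round half away from
zero.

## Tissue specificity

Atlas samples of excluded tissues (brain by default, where cilia presence
is region-dependent) are dropped; each gene is Z-scored across the
retained samples; tissues are ranked by mean signature Z. Per gene,
samples are ranked ascending (average ranks on ties; highest expression =
highest rank) and the statistic is the mean rank of ciliated samples. The
permutation p is upper-tail with add-one correction,
p = (1 + #{permuted ≥ observed})/(1 + n_perm), preventing p = 0; the plain
fraction is available behind a flag. The rank orientation is chosen so
that up-regulation in ciliated tissues yields small p. Each gene uses an
independent, seed-derived random substream, so the table is reproducible
and genes are exchangeable. BH correction is applied across genes. The
default permutation count is configurable: 10⁶ matches the conventional
setting; the test suite and acceptance script use 2×10³–10⁵, which leaves
the add-one floor far below the BH threshold at these problem sizes.

## Differential coexpression

Hubs are module members with MM_ciliary ≥ 0.75 (inclusive). A candidate
gene is a hub in a strict majority (> ½, i.e. ⌊D_t/2⌋+1) of one tissue's
available datasets and a member in no dataset of any other tissue — which
makes candidacy mutually exclusive across tissues by construction. The MM
difference across tissues is tested by one-way fixed-effects ANOVA on
Fisher-transformed (atanh, |r| clamped at 1−10⁻¹⁵) per-dataset MM values;
all datasets with a defined ciliary MM contribute, member or not, because
restricting to member datasets would leave the test undefined for exactly
the genes of interest. BH across candidates. Validation compares the
gene's Z-scored atlas expression in the focal tissue's samples (for the
excluded brain: the 10 samples with highest mean marker Z, the
"ependyma-positive" analog) against the union of the other tissues', with
a two-sided pooled-variance t-test, BH across candidates.

## Synthetic data

The generator plants exactly the structure the analysis assumes. Per
dataset, a latent ciliated fraction c_s ~ Beta(2, 5) (right-skewed,
minority-cell-type-like) is drawn per sample; signature genes follow
x = α_g + β_g f_s + ε with f_s the *standardized* fraction, β_g ~
U(0.5, 1.5) and ε ~ N(0, 1). Standardizing the driver puts β in units of
the noise SD, giving within-signature correlations β_iβ_j/√((β_i²+1)(β_j²+1))
≈ 0.2–0.7 — the regime in which cell-type modules are detectable in real
panels; the raw fractions are kept in the ground truth. Confounder modules
(3 × 100 genes) are built identically from independent factors,
orthogonalized in-sample against the ciliary driver so they carry no
incidental correlation with it. Tissue-restricted hubs load at the top of
the β range in their own tissue's datasets only. 5% of signature genes are
dropped per dataset to exercise availability-aware consensus counting.
Background genes are i.i.d. noise.

The body atlas has 20 tissues (6 ciliated, one brain flagged for
exclusion, ≥ 3 samples each); signature genes are shifted by
`atlas_effect` = 2 noise-SDs (≈ 2 Z units) in ciliated tissues; 10 brain
samples get elevated markers plus the brain-hub effect to exercise
marker-positive sample selection. Non-planted genes have identical means
across tissues by construction. The evidence table is generated to be
consistent with the planted novelty categories.

What the generator does **not** emulate: probe-level effects, batch
structure, heteroskedastic (count-like) noise, correlated backgrounds, or
nonlinear composition effects. Passing tests therefore demonstrate that
the machinery recovers the assumed latent-fraction structure when present,
not that real tissue panels satisfy those assumptions.

## Numerical and design choices

- Correlations computed via `numpy.corrcoef`, clipped to [−1, 1]; ANOVA,
  t-tests, hypergeometric tails and ranking via scipy; BH via statsmodels.
- Per-stage sub-seeds are derived from the global seed by fixed offsets,
  so changing, e.g., the FDR iteration count cannot perturb network
  construction. All seeds stay below 2³¹.
- Degenerate inputs: min_size above the leaf count → all genes unassigned;
  empty modules error; all-singleton ANOVA groups → NA; constant genes are
  dropped before Z-scoring, erroring only when nothing remains.
- Problem sizes in the test suite and acceptance script (2,000-gene
  networks, 2×10⁴ tissue permutations, 1,000 FDR iterations) were chosen
  as the smallest at which every statistical check is comfortably inside
  its Monte-Carlo tolerance.

## Limitations

- The adaptive tree cut is tuned for TOM-style dissimilarities in [0, 1];
  very differently scaled dissimilarities may need the cut fraction and
  gap parameters adjusted.
- The FDR estimate treats per-dataset module draws as independent across
  datasets, as the replacement scheme prescribes; correlated module
  composition across datasets (the interesting biological case) makes the
  estimate conservative for the null but is not modeled.
- Tissue-specificity p-values share the atlas's sample structure; strong
  inter-tissue correlation of signature genes is partially absorbed by the
  per-gene permutation scheme but tissue-level pseudoreplication is not
  modeled.
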
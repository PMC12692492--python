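# Methods

Statistical definitions, default parameters and the reasoning behind the
numerical choices. Section names follow the module layout in
`src/emtmet/`.

## Synthetic data (`simulate`)

All generators draw from named RNG substreams:
`default_rng([seed, crc32(stream_name)])`, so the single-cell, CNV, bulk
and drug generators are independently reproducible and changing one does
not perturb the others. `SimConfig` is a frozen dataclass; invalid fields
raise errors naming the field.

- **Single cell** (`gen_single_cell`): expression is Gaussian on the
  log1p scale around per-gene baselines (`noise_sd = 0.5`); the counts
  layer is `round(expm1(X))`. Planted structure: a latent EMT axis
  `emt_latent ~ U(0,1)` loading additively on 50 EMT genes
  (`emt_gradient_sd = 1.0`); 3 disjoint 50-gene programs, each active
  with a positive random amplitude in ~35% of cells; pseudotime is the
  EMT axis plus small observation noise; metadata (sample, cancer,
  stage, metastatic state, cell type) derives deterministically from the
  latent variables.
- **CNV** (`gen_cnv_matrix`): neutral scores `1 + N(0, 0.05)`; malignant
  cells additionally carry block shifts (+0.3, −0.3, +0.3 over 100-to-
  100-feature windows by default), truncated positive.
- **Bulk** (`gen_bulk`): metastasis label
  `~ Bernoulli(sigmoid(Σ_g ±β·x_g))` over the signature genes with
  per-gene coefficient `±bulk_beta` (sign from the gene's direction).
  The linear predictor is used literally — no scaling by signature size —
  so the label-expression coupling grows with the signature, which is the
  declared contract of the generator.
- **Drug world** (`gen_drug_world`): planted drugs draw 80% of their
  targets from the signature; their treated profiles shift up-signature
  genes by −δ (and down-signature genes by +δ) on the log scale; decoys
  target background genes with null profiles. The PPI backbone is a
  random spanning tree plus extra random edges, so the network is always
  connected.

## Malignancy (`malignancy`)

Per-cell CNV deviation is the mean **squared** deviation from the
neutral score 1 (no square root; an RMS variant is available via
`sqrt=True`, and ranking for the reference curve always uses the MSD so
the two variants pick the same reference cells). The reference curve is
the feature-wise mean over the top 5% of cells by deviation; each cell's
Pearson correlation to the curve is computed vectorized, with NaN for
zero-variance cells. Classification uses strict inequalities:
deviation > 0.002 **and** correlation > 0.1 ⇒ Malignant; both strictly
below ⇒ NotMalignant; anything else (including exact threshold hits) ⇒
Other. A NaN correlation counts as "below threshold", so constant cells
can still be called NotMalignant but never Malignant. When cell types
are supplied, only epithelial cells can be Malignant.

## Signature scoring (`scoring`)

`control_binned_score` follows the module-score recipe: genes are
binned by mean expression (25 rank-based bins), and each set gene's
expression is offset by the mean of `n_ctrl = 100` control genes drawn
from its bin. `ranking_auc_score` ranks genes per cell by expression and
measures the recovery AUC of the set within the top 5%, normalized so a
perfectly packed top scores 1. `scale_01` min-max scales (constant
input maps to 0). `stratify_emt` cuts at the 40%/60% quantiles (linear
interpolation): strictly below Q40 ⇒ lEMT, strictly above Q60 ⇒ hEMT,
boundary values ⇒ mEMT; groups below 5 cells are skipped with a warning.

## Meta-programs (`programs`)

Per sample, NMF (random init) is run for ranks 4–12 with 10 seeded
repeats. Rank selection maximizes the composite
`cophenetic(consensus) − mean relative reconstruction error − 0.01·rank`
with ties to the smaller rank. The cophenetic term rewards repeat-stable
cell clusterings, the error term rewards fit, and the small rank penalty
breaks plateaus toward parsimony; a pure stability criterion is degenerate
(a rank the data does not support can still be perfectly stable), and a
pure error criterion always chooses the maximum rank. Each factor's top
50 genes form a module. Modules are kept when they reach Jaccard > 0.05
with ≥ 5 other modules; genes recurring in ≥ 2 modules form a
co-occurrence graph (edge weight = number of shared modules; weighted
degree ≥ 2 required). Communities come from Infomap
(`igraph.community_infomap`, seeded); singleton communities are dropped.
Programs from different cancers merge by single linkage at
Jaccard > 0.25. The module↔program screen keeps modules with
|Pearson r| > 0.2 **and** p < 0.05 against any program score (strict
inequalities: sample r exactly 0.2 is rejected regardless of p).

## Contrastive DE and trends (`de`)

Anchors are mutual nearest neighbors (k = 5) in a joint 30-PC space;
pair similarity is the Pearson correlation of the paired PC coordinates,
and pairs with similarity > 0.9 are dropped (cells too alike carry no
contrast). DE uses the two-sided Wilcoxon rank-sum test per gene with
`avg_log2FC = log2((mean expm1 + 1)/(mean expm1 + 1))`; genes pass at
p < 0.05 and |lfc| > 0.25, with BH-adjusted p reported alongside.

Pseudotime curves are smoothed with a natural cubic spline
(truncated-power basis, `df = 8`) evaluated on a 100-point grid, then
tested with Mann–Kendall: `τ = S / (n(n−1)/2)`, tie-corrected normal
approximation with continuity correction, and exact p (inversion-count
convolution) for tie-free series of length ≤ 10. `df = 8` rather than a
smoother fit because heavy smoothing manufactures near-monotone curves
from noise: at `df = 5` the joint-threshold null rate was ~4.7%, at
`df = 8` it is ~0.3% with unchanged sensitivity on planted ramps. Trend
genes pass p < 0.05 and |τ| > 0.7 by default (`tau_min = 0.4` available
as a permissive preset).

Signatures: a gene enters a cancer's signature when found by ≥ 2 of the
three gene sets (DE, subtype markers, trends); its direction follows the
DE set first, then trends, then markers. Cross-cancer signatures keep
genes shared by ≥ 3 cancers; genes whose "up" and "down" counts both
reach the threshold are excluded as conflicting.

## Risk model (`model`)

The cohort splits 80/20 stratified. Three feature selectors vote and
genes with ≥ 2 votes are kept:

- **L1 logistic path** at the CV-optimal penalty, scored by held-out
  log-loss (deviance) with the one-standard-error rule. Deviance rather
  than AUC because on uninformative data held-out deviance strictly
  worsens as noise genes enter — the CV optimum is then the null model —
  whereas rank metrics sit flat at chance and pick a penalty at random.
- **Tree-ensemble permutation importance**, measured on an internal
  validation split and calibrated against a label-permutation null
  (Altmann-style): a gene is kept only when its importance exceeds the
  largest importance any gene attains after shuffling the labels. On
  pure noise the data is its own null, so almost nothing passes; planted
  effects exceed the null by an order of magnitude. Without the
  calibration, finite-sample chance correlations make the importance
  ranking agree with the univariate filter even on noise, defeating the
  purpose of intersecting selectors.
- **Univariate rank-AUC** filter, top 35 by |AUC − 0.5|.

Candidate learners (logistic, L2-logistic, gradient boosting — a
pluggable registry) are scored by stratified 5-fold CV AUC and held-out
test AUC and ranked by
`ModelScore = (CV + Test)/2 − 0.8·|CV − Test|`, which penalizes
CV/test divergence. The final MPS/GMPS is the linear predictor
(including intercept) of an unpenalized logistic fit on the selected
genes (tiny-ridge fallback under complete separation); samples above
the median score are High risk (ties ⇒ Low).

## Drugs (`drugs`)

The drug–target and PPI edges form one simple undirected graph
(duplicates collapsed, self-loops and isolated nodes dropped); the
transition matrix is the column-normalized adjacency. RWR iterates
`P ← αAP + (1−α)P₀` (α = 0.7, seed indicator normalized to sum 1) to an
L1 residual below 1e−10; the stationary vector sums to 1 and equals
`(1−α)(I−αA)⁻¹P₀`.

Perturbation contrasts are ranked by the per-gene Welch t statistic
(mean difference when an arm has a single replicate). Pre-ranked GSEA
uses the weighted KS running sum (hit increments ∝ |stat|, uniform miss
decrements), a gene-label permutation null,
`NES = ES / mean(|null ES| of the same sign)`, and the two-sided
permutation p `(#{|null ES| ≥ |ES|} + 1)/(n_perm + 1)` — uniform under
the null with floor `1/(n_perm+1)`. `Score_GSEA = minmax(−NES)` across
drugs, `Score_RWR = minmax` of the drugs' stationary probabilities, and
`DrugScore = 0.6·Score_RWR + 0.4·Score_GSEA` over the drugs scored by
both channels. Effect is "inhibits" iff NES < 0. `perturbation_mps_test`
reports the difference of median MPS (treated − control) and the
two-sided Wilcoxon rank-sum p.

## Scope and limits of the generators

The synthetic worlds are deliberately simple: Gaussian log-scale noise
(no over-dispersion or dropout), independent cells, linear latent
loadings, and block-structured programs. They are designed to make the
planted parameters identifiable by the intended estimators, not to
mimic real scRNA-seq noise; recovery numbers on them are upper bounds
on real-data performance. Fold-change-based thresholds were tuned to
the statistics of these worlds' log-scale means and may need revisiting
for depth-normalized real data.
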
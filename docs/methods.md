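# Methods

This note records the statistical models the package implements, the choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not establish.

## Single-sample enrichment score

The per-sample signature score is an integrated, rank-weighted running sum
(the ssGSEA family). Per sample, genes are ranked by descending expression
with average ranks on ties; walking the ranked list, an in-set gene at rank
r advances the hit curve by (G − r + 1)^α normalised by the in-set total,
an out-of-set gene advances the miss curve by 1/(G − m) (G genes in the
matrix, m set genes present); the score is the sum of hit − miss over all G
positions. α defaults to 0.25 (the ssGSEA convention; α = 0 reduces to an
unweighted Kolmogorov–Smirnov walk). The statistic is invariant to any
monotone transform of a sample's expression vector and to gene order, which
is exactly the property the downstream uses (correlation, averaging, group
contrasts) require. We deliberately do not reproduce kernel-smoothed
ECDF-based variants of single-sample scoring: they differ from the running
sum by a monotone-in-rank reweighting, and no downstream quantity here
depends on more than a monotone per-set score. Ties use average ranks so
that scoring is deterministic and symmetric; scoring requires at least 2 set
genes in the matrix (configurable) and refuses a set that covers the whole
matrix.

## Endothelial abundance

Two estimates play the role of deconvolution- and signature-based abundance:

1. **Constrained least squares**: per sample, min ‖Rf − b‖₂ subject to
   f ≥ 0 and Σf ≤ 1, with R the linear-scale reference profiles (user
   supplied; must contain an `endothelial` column) restricted to shared
   genes, and b the linear-scale sample (log2(x+1) inputs are inverted
   first). The solver runs NNLS; when the unconstrained-sum NNLS optimum
   already satisfies Σf ≤ 1 it is the constrained optimum, otherwise the
   problem is re-solved on the face Σf = 1 with SLSQP. Rank-deficient
   references yield a warning and a pseudo-solution.
2. **Marker enrichment**: the running-sum score of an endothelial marker
   set.

## Composite angiogenesis score

The composite is the arithmetic mean of six features: four angiogenesis
pathway enrichment scores plus the two endothelial-abundance estimates.
Because enrichment scores and fractions live on incommensurate scales, each
feature is z-scored across samples (ddof = 1) before averaging; the
`standardize` flag turns this off for users who want the raw average.
A feature constant across samples carries no contrast and is dropped with a
warning under standardization.

## Subtype assignment

Histologic rules are applied verbatim: soft & hot (TIIC ≥ 3, fibrosis 0–1),
armored & cold (TIIC ≤ 2, fibrosis 2–3), quiescent (TIIC ≤ 2, fibrosis
0–1); the uncovered corner (TIIC ≥ 3, fibrosis 2–3) is reported
`unclassified` rather than forced into a group.

Transcriptomic assignment uses two cutpoints: immune ≥ cut → soft & hot,
else collagen ≥ cut → armored & cold, else quiescent. Samples high on both
axes are folded into soft & hot by default (they are rare and immune
dominates the published three-group figures); `high_high="unclassified"`
flags them instead. Cutpoints are a declared parameter: absolute values,
per-cohort quantiles (default medians; quantile cuts make the assignment
invariant to common monotone transforms of both scores), or `bimodal` — the
midpoint between the two 1-D 2-means cluster centres, found by an exact
threshold sweep. The bimodal option exists because fixed-quantile cuts
misassign whenever the realized subtype counts fluctuate around their
expectations (the cut then lands inside a score cluster); when a score
distribution has a genuine high/low gap the gap midpoint is the natural
boundary. On unimodal scores `bimodal` degenerates to an arbitrary interior
split and medians should be preferred.

## Differential expression and enrichment

Per-gene Welch two-sample t on log2 values; fold change is linear,
2^(mean_A − mean_B); the association gate is raw p < 0.05 AND FC ≥ 1.5 (or
≤ 1/1.5, direction-flagged). Empirical-Bayes variance moderation is
intentionally not used: the gate is a threshold rule, not a
moderation-specific claim, and Welch t is exactly reproducible; a
Benjamini–Hochberg column is emitted for users who want FDR control (the
gate itself uses raw p, matching the published rule). Genes with zero
variance in both groups get p = 1 (equal means) or p → 0 (unequal means).

Preranked GSEA uses the weighted KS running sum with weight exponent 1
(in-set steps ∝ |ranking weight|), ES = signed maximum deviation, and a
gene-label permutation null (random same-size sets), which is deterministic
under a seed at desk scale; phenotype permutation would require
re-computing the ranking per permutation and is out of scope. NES divides
ES by the mean |null ES| of matching sign; p is the add-one estimate among
same-sign nulls, so its floor is 1/(#same-sign + 1). With no same-sign
permutations p is reported at the floor with a warning. Over-representation
is the one-sided upper hypergeometric tail on the 2×2 table within the
declared universe; the odds ratio takes the Haldane 0.5 correction on zero
cells.

## Single-cell processing

QC keeps a cell iff mito fraction ≤ 0.10 AND 200 ≤ detected genes ≤ 5000
(defaults; boundaries inclusive — only strict exceedance excludes, matching
the rule's wording). Mitochondrial genes are identified by the configurable
`MT-` prefix so the fraction is recomputable from the matrix itself; QC is
idempotent. Normalisation is library-size scaling to a common total (10⁴)
then log1p; the top-n (default 4000) genes by variance of the log values
are centred and reduced by exact-SVD PCA to 40 components (both reduced
with a warning when the data are smaller). Batch structure is handled, if
requested, by per-batch centering of the embedding — a deliberately simple
linear surrogate for iterative integration methods, adequate for the
location shifts the generator plants and clearly not for nonlinear batch
distortions. Clustering is Leiden community detection on a symmetrised kNN
graph (seeded; resolution 1.0), with seeded k-means as the fallback
backend; each cluster is labelled by the cell type whose markers have the
highest mean z-scored log expression in the cluster, ties broken
lexicographically with a warning.

The ligand–receptor test scores an ordered type pair (A→B) and pair (L,R)
as ½(mean L in A + mean R in B) on log-normalised expression, gated to
score 0 / p 1 when either gene is expressed in under 10% of its cluster
(the gate convention of the standard interaction tool; multi-subunit
complexes are not modelled). The null permutes cell-type labels n_perm
times (default 1000); p = (1 + #{null ≥ observed})/(1 + n_perm), so p never
falls below 1/(n_perm + 1). Cells are put in canonical (ID-sorted) order
before drawing permutations, making results exactly invariant to row order
at fixed seed. The headline summary is the matrix of significant-pair
counts (p < 0.05) over ordered type pairs.

## Spatial proximity

The implemented statistic is the nearest-neighbour Euclidean distance from
each source spot (endothelial) to the nearest spot of a target type, via a
k-d tree, with self-exclusion when source and target types coincide. Mean
pairwise distance is available behind `metric="mean_pairwise"`;
nearest-neighbour is the default because it operationalises "positioned
closer to" directly and is less dominated by the far tail. Comparisons are
two-sided Mann–Whitney (asymptotic, tie-corrected; complete ties give
p = 1) between distances to the reference type and either the pooled
nearest non-reference distance (`pooled`, default) or each other type
separately (`per-type`). Samples are summarised independently — array
coordinates are not comparable across samples, so distances are never
pooled. One caveat is inherent to the statistic: nearest-distance
distributions shift with target abundance alone, so the pooled Mann–Whitney
null is exchangeable only when reference and comparison targets have
comparable spot counts; calibration runs therefore use equal abundance, and
real-data comparisons across types with very different abundances should be
read as descriptive.

## Survival and response

Kaplan–Meier estimation and log-rank testing (k-group, k−1 df) are
delegated to lifelines; at tied times, censoring is taken to occur after
events (the standard convention). Marker dichotomization splits at the
median with at-median values going **low** (strictly above → high), so 65
distinct values split 33/32; the `mirror` flag flips the tie side. The rule
is deterministic under heavy ties even when the resulting groups are
unbalanced. Response tables get ORR per arm and a χ² homogeneity test
without continuity correction, falling back to Fisher's exact test on 2×2
tables when any expected cell is below 5 or the total sample is under 40
(Cochran's conditions).

## Synthetic cohorts: what they emulate

The generators define the study conditions for all tests; all are
deterministic under their seed.

- **Bulk** (`BulkSimConfig`): genes × samples on log2 scale, Gaussian noise
  (sd 0.5), baselines uniform on [4, 8]. The gene universe is partitioned
  into collagen (40), immune (40), four angiogenesis pathway subsets plus
  an endothelial marker set (12 each) and background. Subtype labels are
  multinomial (default 50/25/25% quiescent/armored/soft). Per sample, a
  latent collagen activity c_s = effect·1[armored] + noise_sd·η_s shifts
  the collagen block, and the angiogenesis blocks shift by coupling·c_s —
  so the collagen–angiogenesis correlation is planted, tunable and
  continuous within groups; at zero effects and coupling the global null is
  exact. Default shifts are 4.0 log2 units: with the measurement noise the
  enrichment scores carry, this is the regime in which the score clusters
  are separated by ≈6.5 sd, i.e. genuinely "large" planted effects whose
  recovery is limited by the method, not the generator. Data are generated
  directly on log2 scale (not as counts) because the bulk analyses operate
  on processed matrices.
- **Single cell** (`SCSimConfig`): negative-binomial counts (gamma–Poisson,
  size parameter 2) with a 20-gene marker block per type at mean 20,
  background mean 1, and 10 `MT-` genes whose per-cell mean is set so the
  realised mitochondrial fraction matches a per-type Gaussian target —
  making the QC structure plantable. Planted ligand/receptor genes sit at
  their effect mean only in their source/target type and are near-silent
  (mean 0.02) elsewhere, as the expressed-fraction gate presumes.
- **Spatial** (`SpatialSimConfig`): fibroblast and other spots uniform on a
  square field (default 100 units); endothelial spots are Gaussian
  displacements (sd `coloc_sd`, default 2) around uniformly chosen
  fibroblast anchors, clipped to the field; `coloc_sd=None`/∞ encodes the
  uniform null.
- **Survival** (`SurvSimConfig`): exponential event times per group with
  independent exponential censoring — the simplest mechanism with
  closed-form expectations (default hazards 0.05 vs 0.20, censoring 0.02).

What passing tests show — and what they do not: the planted cohorts have
independent Gaussian/NB noise, block-structured signals and no confounding,
so recovery and calibration results certify the *statistical machinery*
(correct statistics, valid permutation nulls, faithful rules), not
robustness to correlated genes, batch effects, compositional distortions,
doublets, segmentation errors or informative censoring found in real data.

## Problem sizes and numerical choices

Simulated analyses use desk-scale cohorts chosen to make every planted
effect decisively detectable while keeping the full suite fast: bulk n=400
samples × 300 genes, single-cell 800 cells × 200 genes, 12 spatial samples
of ~130 spots, survival 200/group; null calibrations use 500 replicates
and permutation tests 200–1000 permutations. Add-one permutation p-values
are used throughout (never exactly zero). Degenerate inputs are handled
explicitly rather than propagating NaN: zero-variance correlations raise,
zero between-group variance gives F = 0/p = 1, complete spatial ties give
p = 1, all-identical markers refuse to split.

## Known limitations

- The subtype cutpoints on transcriptomic scores are cohort-derived; no
  external calibration of "high collagen" is attempted.
- The deconvolution is a plain constrained regression: no tumor-content
  renormalisation, no marker weighting, no uncertainty.
- The LR test ignores multi-subunit receptor complexes and database
  curation; it tests only the supplied pair list.
- Spatial spots carry one label each; deconvolved multi-label spots are out
  of scope, and cross-type abundance differences bias nearest-distance
  comparisons (see above).
- No Cox regression; group-level survival contrasts only.
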
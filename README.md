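# collangio

Analysis pipeline linking intratumoral collagen to angiogenesis in the tumor
microenvironment. Tumors are stratified into three *immuno-collagenic*
subtypes — **armored & cold** (collagen-high, immune-low), **soft & hot**
(immune-high, fibrosis-low) and **quiescent** (both low) — and the pipeline
quantifies how angiogenesis tracks the collagen program across bulk
transcriptomes, single cells, spatial arrays and survival cohorts. It is
aimed at computational biologists who want the full analysis chain
reproducible and testable on synthetic cohorts with planted ground truth
before pointing it at real data.

## What it computes

**Signature scoring.** Per-sample single-sample gene-set enrichment (ssGSEA
family): genes are ranked per sample by descending expression and the score
integrates the weighted running sum

&nbsp;&nbsp;ES(S, sample) = Σ_i [ P_hit(i) − P_miss(i) ],&nbsp;
P_hit steps ∝ (G − rank + 1)^α for genes in S, P_miss steps = 1/(G − |S|),

with α = 0.25. The score depends on within-sample ranks only. The
**composite angiogenesis score** averages six per-sample features — four
angiogenesis pathway enrichment scores plus two endothelial-abundance
estimates (a constrained-least-squares deconvolution fraction
min‖Rf − b‖₂ s.t. f ≥ 0, Σf ≤ 1, and an endothelial marker enrichment
score) — after z-scoring each feature across samples.

**Subtyping.** From histology: soft & hot ⇔ TIIC ≥ 3 and fibrosis 0–1;
armored & cold ⇔ TIIC ≤ 2 and fibrosis 2–3; quiescent ⇔ TIIC ≤ 2 and
fibrosis 0–1; anything else unclassified. From transcriptomic scores:
cutpoint rules on collagen and immune scores (median, quantile, or bimodal
gap cutpoints). Discrimination is summarised by ROC AUC
(= P(score⁺ > score⁻) + ½P(tie)), group contrasts by ANOVA/Tukey or
Kruskal–Wallis/Dunn.

**Differential enrichment.** Welch t per gene on log2 values; a gene is
subtype-associated when p < 0.05 and linear fold change ≥ 1.5. Preranked
GSEA (maximum-deviation weighted Kolmogorov–Smirnov running sum, gene-label
permutation null, NES = ES / mean |null ES| of matching sign) and one-sided
hypergeometric over-representation.

**Single cell.** QC (drop cells with mitochondrial fraction > 10% or
detected genes outside [200, 5000]), library-size normalisation, PCA on the
top variable genes, Leiden clustering on a kNN graph, marker-based
annotation, and a ligand–receptor test: score(A→B; L,R) =
½(mean L in A + mean R in B), nulled by permuting cell-type labels, with a
10% expressed-fraction gate.

**Spatial.** Nearest-neighbour Euclidean distance from each endothelial spot
to each target cell type; co-localization tested by two-sided Mann–Whitney
against distances to non-fibroblast types, per sample (never pooled across
arrays).

**Survival.** Kaplan–Meier product-limit curves, log-rank tests (k groups),
median dichotomization of continuous markers, and χ²/Fisher response-rate
tests.

Every input has a synthetic generator with planted ground truth
(`collangio.synthetic`), so each stage's recovery and calibration are
testable end to end.

## Worked example

The numbered scripts under `analysis/` run the study on synthetic cohorts
and write tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_score_and_subtype.py
python analysis/03_differential_enrichment.py
python analysis/04_single_cell_interactions.py
python analysis/05_spatial_proximity.py
python analysis/06_survival.py
```

which prints, among other lines:

```
transcriptomic subtype calls agree with planted labels for 99.5% of 400 samples
composite angiogenesis score by subtype (ANOVA p = 7.13e-175): armored_cold 1.45, quiescent -0.27, soft_hot -0.81
100 genes flagged as armored & cold-associated (p < 0.05 and FC >= 1.5, up in armored & cold) of 300
GSEA on the signed-t ranking: top set COLLAGEN_PROGRAM (ES 0.77, NES 1.34, p 9.99e-04)
most significant ligand-receptor pairs between fibroblast -> endothelial (5 of 5 pairs, p < 0.05 by label permutation)
12/12 samples place endothelial spots closer to fibroblasts than to other types; 12 significant at p < 0.01
log-rank chi-square 112.2, p = 3.24e-26; median survival low: 11.5, high: 3.6
```

Read: the planted subtypes are recovered almost perfectly; the armored &
cold group carries the highest composite angiogenesis score; exactly the
planted collagen+angiogenesis genes pass the DEG gate; the planted
fibroblast→endothelial signalling and spatial co-localization are detected
in every sample; and the planted hazard ratio of 4 yields the expected
log-rank separation. `analysis/07_full_pipeline.py` runs the same chain from
a single YAML config with provenance-stamped, byte-reproducible outputs.

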
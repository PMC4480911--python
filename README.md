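# spikeflow

Spike-in-anchored expression profiling for tag-count RNA-seq.

## The problem

Bulk and single-cell comparisons of cell states routinely assume that every
sample carries the same amount of mRNA per unit total RNA. For keratinocytes
this is false: actively growing cultured cells contain roughly twice the
polyA+ RNA of differentiated epidermal tissue, and late-passage or
immortalized cells sit in between. Classical total-count ("endogenous
gene-based") normalization silently rescales this real global difference
away — and, worse, makes truly constant features look differentially
expressed. When synthetic polyA+ spike-in RNAs are added in a fixed amount
per sample before library preparation, their counts anchor an absolute
per-sample scale that survives content fluctuations.

`spikeflow` implements that analysis chain for gene × sample count matrices
with spike-in features flagged by an id prefix:

1. **Relative polyA+ content** per sample: `content_s = Σ endogenous counts / Σ spike counts`,
   with a k·MAD outlier screen within comparison groups and Spearman
   replicate-concordance QC.
2. **Depth normalization** by spike-in sums (or endogenous sums, for
   contrast): `x̃_gs = x_gs · mean(d)/d_s`.
3. **SAM-style resampling differential expression**: counts are
   Poisson-downsampled to the minimum depth (`d_s = min(d)/d_s`), a rank
   statistic is averaged over resamples — standardized Wilcoxon rank-sum
   (two-class), Kruskal–Wallis (multiclass), or standardized Spearman
   correlation `z = ρ√(n−1)` (quantitative) — and per-gene **local FDR** is
   estimated as `lfdr(z) = π₀ f₀(z)/f(z)` from a response-permutation null.
4. **Scaled, non-centered PCA**: each gene row is divided by its standard
   deviation but *not* centered; components come from the SVD of the
   preprocessed matrix, with per-component contribution ratios
   `λ_c/Σλ · 100 %`, loading z-scores, and three-sigma (|z| > 3) extraction
   of contributing genes.
5. **PC-GSEA**: genes ranked by their quantitative-response correlation with
   a component feed a preranked GSEA (weighted Kolmogorov–Smirnov enrichment
   score, gene-label permutation null, sign-stratified NES and FDR q).

A synthetic-data generator reproduces the statistical structure this chain
assumes — fixed spike-in input, type-dependent content multipliers, planted
fold changes with known truth — so every stage is testable without any
download.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
cohorts (`python analysis/01_simulate_cohort.py`, then 02…05). The
normalization contrast (script 03) prints:

```
 norm_mode feature_class  median_fold_ekc_vs_sg
endogenous      spike-in                 0.5146
endogenous    endogenous                 1.0365
     spike      spike-in                 0.9971
     spike    endogenous                 2.0179
```

Reading: the simulated early-passage cells (EKC) truly contain 2× the mRNA
of tissue (SG). Total-count normalization flattens the genuine endogenous
shift to ~1 and drags the constant spike-ins down to ~0.5 — the classic
artifact — while spike-in normalization keeps spikes at ~1 and reveals the
real ~2× endogenous fold. Script 05 reports the operating characteristics:

```
                       quantity  value unit
null_genes_below_1pct_local_fdr  0.000    %
      sensitivity_planted_4fold 96.000    %
         gsea_planted_top20_nes  3.203  NES
    gsea_null_sets_below_1pct_q  0.000    %
```

The same chain is available as a CLI (`spikeflow simulate / qc / normalize /
detest / pca / gsea / run`); `spikeflow run --config run.yaml` executes the
whole pipeline and writes one TSV per stage plus a run manifest.

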
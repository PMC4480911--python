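# Methods

## Model and rationale

The package analyses tag-count RNA-seq data (5' tag counting; no transcript
length term) in which synthetic polyA+ spike-in RNAs were added in a fixed
amount per sample. Because the spike-in input is constant, the per-sample sum
of spike-in counts estimates the sequencing yield per unit input RNA, and

    content_s = (Σ endogenous counts in s) / (Σ spike-in counts in s)

estimates the relative polyA+ mRNA content of sample `s` per unit total RNA.
This quantity is invariant to rescaling all counts of a sample and is the
package's basic QC/normalization primitive. Depth normalization multiplies
each sample by `mean(depths)/depth_s`, where depth is either the spike-in sum
(content-robust) or the endogenous sum (classical total-count; kept for the
methodological contrast it enables).

### Resampling rank tests

Differential expression follows the SAM resampling approach adapted to
anchored depths. All samples are Poisson-downsampled to the minimum depth
(factor `d_s = min(depth)/depth_s`; counts at factor 1 are kept verbatim so no
noise enters the reference sample; zeros stay zero). On each of
`n_resamples` (default 20) resampled matrices a mid-rank statistic is
computed per endogenous gene and averaged:

* two-class: standardized Wilcoxon rank-sum. Ties are handled through the
  finite-population variance `Var(W) = n₁n₂/(N(N−1)) · Σ(rᵢ − r̄)²`, which
  reduces to the classical `n₁n₂(N+1)/12` without ties.
* multiclass: Kruskal–Wallis `H = (N−1) Σ nⱼ(R̄ⱼ − r̄)² / Σ(rᵢ − r̄)²`
  (tie-corrected by construction; unsigned, so no direction is reported).
* quantitative: Spearman correlation standardized as `z = ρ√(N−1)`.

The null distribution permutes the response `n_perms` times (default 100) and
reuses the same resampled stacks, so the permutation null reflects exactly
the same resampling noise as the observed scores.

### Local FDR

Per-gene local FDR is the density ratio `lfdr(z) = π₀ f₀(z)/f(z)` with `f₀`
a Gaussian kernel density over the pooled permutation scores and `f` over
the observed scores, both evaluated on a shared 512-point grid. Both
densities use the *same* absolute bandwidth, taken from the (much larger)
permutation pool via Scott's rule; unequal bandwidths would bias the ratio
away from 1 under the null. `π₀` is the ratio of observed to permuted mass
inside the central region (|score| below the median absolute permuted
score), clipped to (0, 1]. Pools larger than 20,000 scores are thinned
deterministically by evenly spaced order statistics. Identical scores get
identical local FDR; fewer than 50 permuted scores is an error. The
estimator is intentionally simple; its pointwise values wiggle by ±0.2 under
the null (finite-sample KDE), but calibration at the 1 % decision threshold
is what the tests pin down.

### Non-centered scaled PCA

Each gene row of the (spike-normalized, by default log1p-transformed)
expression matrix is divided by its population standard deviation without
mean subtraction, then decomposed by SVD. Skipping the centering keeps the
common expression offset in the model: the leading component absorbs overall
expression magnitude, which is exactly the axis on which samples with
different absolute polyA+ content separate. Contribution ratios are
eigenvalue shares of the full uncentered spectrum (summing to 100 % over all
components). Component signs are fixed by making the largest-magnitude
loading positive. Loading z-scores standardize one component's loadings over
all retained genes; the three-sigma rule (|z| > 3, configurable) extracts the
genes that drive a component. Per-gene correlation with a component reuses
the quantitative resampling test with the component's sample scores as the
response. Spike-ins are excluded from the PCA input (they would otherwise
dominate the uncentered fit) but still drive depth estimation.

### Preranked GSEA

For a list of `N` genes ranked by descending signed score, the enrichment
score of a set with `m` members walks the list adding
`|score|^p / Σ_hits |score|^p` per member (p = 1 by default) and subtracting
`1/(N − m)` per non-member; ES is the extremum of the running sum (positive
deviation wins an exact magnitude tie; ties in scores keep input order via
stable sorting). The null permutes gene labels (`n_perm` = 1000), shared
between sets of equal size. NES divides ES by the mean |null ES| of matching
sign and size; FDR q is the sign-stratified ratio of null to observed tail
fractions, clipped to [0, 1] and made monotone within each sign by a running
minimum from the least extreme set toward the most extreme (as in step-up
corrections). Size filters default to [15, 500] members present in the list.

## Synthetic data generator

The generator emulates the study design the analysis targets: epidermal
tissue (SG), early/late-passage cultured keratinocytes (EKC/LKC) and an
immortalized line (HaCaT), profiled as technical replicates with fixed
spike-in input. For sample `s` of type `t`:

    E[endogenous count g,s] = depth_s · content_t · θ_g · 2^{log2fc_{g,t}}
    E[spike count k,s]      = depth_s · a_k

with baseline abundances `θ` log-normal (σ = 1.5 on the natural log,
normalized to a simplex), spike abundances `a_k` spanning three orders of
magnitude in log space and summing to 10 % of a unit-content sample's reads,
and depths log-normal (σ = 0.1) around `depth_mean`. Counts are Poisson, or
gamma-Poisson with a single global dispersion (default 0.05 — mild
extra-Poisson noise of technical replicates plus residual biological
variation). The default `depth_mean` of 10⁶ reads over ~2,000 genes keeps
reads-per-gene at the order of magnitude of a bulk tag-count study scaled to
desk size.

Content multipliers are anchored at EKC = 2 × SG, with LKC = HaCaT fixed at
1.4 — the ordering EKC > LKC = HaCaT > SG is structural, the 1.4 an
intermediate choice within the admissible (1, 2) interval. Planted DE genes
(fraction `de_fraction`, default 0.1) each perturb one sample type by a
log2 fold change drawn from `de_log2fc_range` with random sign. The
`four_types` preset plants programs at the prevalence such studies actually
report (30 % of genes, |log2FC| ∈ [1, 3]) and routes half of them to the
tissue type (`tissue_type="SG"`, weight 0.5): differentiation-versus-culture
is the dominant transcriptional axis being emulated. Fold changes are exact
in `θ`; consequently the endogenous/spike expectation-sum ratio between two
types equals the content-multiplier ratio only up to an O(de_fraction)
factor (random signs make it ≈ 1 for the two-group preset; with 30 %
planted genes and heavy-tailed `θ` the realized ratio can drift by ~10 %).
We chose exact planted fold changes over an exact sum ratio because the
power analyses depend on the former.

The outlier mechanism re-draws one sample's endogenous counts as
Poisson(boost × observed count), leaving spike-ins untouched — an inflated
relative-content sample of the kind excluded during study QC.

What the generator does **not** model: donor-level random effects, per-gene
dispersion, gene–gene correlation beyond the planted programs, ambient or
mapping noise, and spike-to-endogenous capture-efficiency differences.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to every artifact of real libraries.

## Numerical and design choices

* Depths are plain count sums; resampling is Poisson (not binomial
  subsampling), matching the resampling-test convention.
* The two-class statistic's positive direction is "higher in the
  lexicographically later class"; multiclass scores are unsigned.
* The outlier screen flags deviations > k·MAD (k = 5) from the group median,
  with the scale floored at 5 % of the group median: with few replicates the
  MAD can collapse below sampling noise, and the floor prevents flagging
  ordinary variation (at the defaults a flag requires a ≥ 25 % deviation).
  Groups below 3 samples are skipped.
* Replicate concordance is Spearman on log1p counts (rank-robust for
  counts); pairs are formed within (donor, sample_type).
* PCA input is log1p-transformed by default (variance stabilization across
  three decades of counts); `--no-log`/`log_transform=False` disables it.
  Gene scaling uses the population (ddof = 0) standard deviation so loading
  z-scores are exactly reproducible.
* All pipeline stage seeds derive from the run seed via fixed-path
  `SeedSequence` spawning and never from the data, which is what makes
  automatic outlier exclusion byte-identical to manual sample removal.
* Pipeline outputs carry a `# spikeflow <version> seed=<seed>` header and no
  timestamps, so re-runs are byte-identical.
* Tissue-separation on the leading component is a stochastic property of the
  generator; tests evaluate it as the median silhouette over three generator
  seeds.
* Problem sizes in tests and the acceptance script (500–2,000 genes, 12–24
  samples, 10 generator seeds for calibration, 500–1,000 enrichment
  permutations) were chosen as the smallest sizes at which the measured
  quantities are stable across seeds.

## Limitations

* The local-FDR estimator is a documented stand-in for the original
  published implementations, whose exact estimator and score scaling are not
  restated in the literature this package draws on; printed score/FDR values
  from those tools are treated as scale references, not targets.
* Multiclass tests report no per-class direction; callers needing directions
  should follow up with two-class contrasts.
* No covariate adjustment, paired designs, negative-binomial GLMs, TMM or
  length normalization — deliberately out of scope for 5' tag counting.
* GSEA supports gene-label permutation only (the preranked mode's null);
  phenotype permutation and leading-edge extraction are not implemented.
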
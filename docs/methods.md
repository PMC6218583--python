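# Methods

`txsig` implements the in-silico arm of a transcription-factor
overexpression study design: four conditions, each compared against one
shared control, analyzed through differential ranking, cross-contrast
signature extraction, consistency-filtered pre-ranked gene-set
enrichment, and connectivity scoring of up/down query signatures against
reference expression profiles.  This note records the models, the
parameters that matter, and the choices made where the design was
genuinely open.

## Differential expression

Counts are modeled as negative binomial with mean `mu` and variance
`mu + alpha * mu^2`.  Per contrast:

- **Filtering.** A gene is kept when its raw count is strictly above 5
  in strictly more than half of *all* samples (all conditions pooled).
  Both comparisons are deliberately strict; the rule is configurable via
  `min_count`.
- **Normalization.** Median-of-ratios size factors (median over genes
  with a strictly positive geometric mean of count / geometric mean),
  rescaled to geometric mean 1.  No pseudo-reference fallback is
  applied: a matrix with no gene positive in every sample is an error.
- **Fold change.** `log2((mean_cond + 0.5) / (mean_ctrl + 0.5))` on
  normalized counts; the 0.5 pseudocount handles zero means.
- **Dispersion.** Per-gene method-of-moments estimates on normalized
  counts pooled across the two groups are shrunk toward a common
  dispersion with an empirical-Bayes-style weight
  `(d_res * max(alpha_g, 0) + d0 * alpha_common) / (d_res + d0)`, prior
  df `d0 = 20`, floor `1e-8`.  With triplicates the raw estimate has 4
  residual df; information sharing across genes is what makes the
  statistic usable, for the same reason the standard count-based DE
  tools shrink dispersions.  The common dispersion is the clipped mean
  (clip to [-0.5, 5]) of the raw per-gene estimates: the more obvious
  median is biased low on few df (the sampling distribution of a
  4-df variance estimate is right-skewed), and that bias propagates
  into every standard error.
- **Statistic.** Wald `stat = log2fc / SE`, with `SE` from the NB
  mean-variance relation by the delta method.  The signed statistic is
  the ranking key for every downstream stage.
- **p-values.** At n=3 per group the Wald statistic is visibly
  heavier-tailed than standard normal — its plug-in SE is correlated
  with the observed means — and normal-tail p-values reject ~7% of null
  genes at the 5% level.  p-values therefore come from a *stratified
  parametric bootstrap*: genes are binned by fitted mean (up to 20
  bins); per bin, null genes are simulated from the fitted NB model
  (means resampled from the bin, common dispersion), pushed through the
  identical statistic computation, and each observed |stat| is referred
  to its bin's |null| tail, `p = (1 + #{|null| >= |stat|}) / (1 + B)`.
  This is exactly calibrated within the model family — the bundled
  checks verify a ~5% rejection rate at alpha=0.05 and KS uniformity of
  the pooled p-distribution across null simulations — and approximately
  calibrated otherwise.  The bootstrap is seeded and canonicalizes group
  sizes, so results are deterministic and exactly invariant under
  swapping condition and control.  `p_method="normal"` restores the
  plain normal tail.
- **FDR.** Benjamini-Hochberg over all tested genes
  (`scipy.stats.false_discovery_control`).

Not implemented (out of scope): outlier replacement (Cook's distance),
independent filtering, LFC shrinkage, multi-factor designs.

## Signatures

DEGs are called at `fdr < 0.10` (strict; the threshold itself is
configurable) with direction from the sign of the statistic; genes with
statistic exactly zero are never called.  The common signature is the
per-direction intersection over all contrasts; a gene up in some
contrasts and down in others lands in neither set (the conservative
reading).  The query signature takes the top `k = 75` and bottom `k`
genes of the statistic ranking; `2k` may equal the number of genes
(the blocks then partition the list) but may not exceed it.  Every
ranking in the package breaks ties by ascending gene identifier, making
all outputs reproducible to the byte.

## Pre-ranked enrichment

Gene sets are intersected with the ranked universe and kept when the
effective size lies in `[15, 250]` (inclusive).  The enrichment score is
the classic weighted KS running sum: hit steps proportional to
`|stat|^weight` (default weight 1), miss steps uniform, score = signed
deviation of maximal magnitude, positive preferred on exact-magnitude
ties.  The leading edge contains the members at or before the extremum
(strictly after it for negative scores).

The null model permutes gene labels — random sets of identical
effective size drawn from the universe — the standard choice for
pre-ranked enrichment, where no sample labels exist to permute.
`NES = ES / mean(|null ES| of same-sign nulls)`;
`p = (1 + k) / (1 + m)` over same-sign nulls, with a floored p and a
warning in the degenerate no-same-sign case.  FDR across pathways is
Benjamini-Hochberg on the permutation p-values per contrast; the
classical GSEA FDR-q procedure is a documented alternative that is not
implemented.  Same-size sets within one contrast share a single null
sample (a pure computational cache; results for each set are as if
drawn independently, and the per-size null uses its own stream).

Redundancy pruning is greedy: sets ordered by best (smallest) p across
contrasts (ties: larger mean |NES|, then name), accepted when the
Jaccard index with every accepted set stays below 0.5 (configurable).
A pathway is *consistent* when its NES sign is identical and nonzero
and its FDR is below 0.10 in all contrasts; consistent pathways are
ranked by mean |NES| and at most 25 are kept.  The display score is
`ES * -log10(p)` (the signed ES value, not just its sign).

## Connectivity

The one-sided statistic is the classic connectivity-map KS tag score:
with matched tags at 1-based positions `V(1) < ... < V(t)` among `n`
genes, `a = max_j(j/t - V(j)/n)`, `b = max_j(V(j)/n - (j-1)/t)`, score
`a` if `a >= b` else `-b`.  Note the statistic is asymmetric at the
`1/n` scale (tags at the exact top of a 10-gene list score +0.7, tags
at the exact bottom -0.8); this is inherent to the step conventions of
the two one-sided suprema.

The combined score is 0 when the up- and down-block scores share a
sign, otherwise `(es_up - es_down) / 2`, rescaled by the maximum raw
value attainable for the matched block sizes (up-tags packed at the
exact top, down-tags at the exact bottom), so perfect concordance
scores exactly +1 and perfect discordance exactly -1.  The `1/n`
asymmetries of the one-sided statistics cancel in the combined score,
which reverses sign exactly under profile reversal (away from tie
degeneracies).  Profiles are scored independently rather than rescaled
as a batch, because reference profiles arrive one per dataset, not as a
ranked library; the raw components are reported so a batch convention
can be recovered.  Query genes missing from a profile are dropped with
a logged count (cross-platform coverage differs); matched counts are
part of the result.

Significance: null scores from random disjoint (up, down) position-set
pairs of the matched sizes; two-sided by magnitude,
`p = (1 + #{|null| >= |obs|}) / (1 + n_perm)`.

## Synthetic data generator

The generator emulates the study conditions so every stage can be
tested against exact planted truth:

- **Counts.** NB with shared dispersion 0.05; baseline means log-normal
  (`meanlog 6.0`, `sdlog 1.0`, i.e. median ~400 counts per gene —
  libraries of a few to ten million assigned reads over ~14k genes,
  ordinary bulk depth, chosen so that essentially the whole universe
  clears the count filter: the default 13,716 genes represent the
  *post-filter* universe).  Per-sample library factors log-normal with
  sdlog 0.15.  Defaults: 4 overexpression conditions + control,
  triplicates; 112 shared-up and 163 shared-down genes perturbed by
  `2^±1.5` in every overexpression condition; 50 extra genes per
  condition (25 up / 25 down) perturbed in that condition only.
- **Gene sets.** One set enriched in shared-up genes, 24 in shared-down
  genes (15-40 planted members each, filled with unperturbed genes to a
  size in [15, 120]), 25 null sets of unperturbed genes, all sizes
  within [15, 250]; optionally a near-duplicate of one null set
  (Jaccard >= 0.5) to exercise redundancy pruning.  Null sets avoid
  planted genes deliberately: planted genes sit at the extreme ends of
  every contrast ranking, so a "null" set containing them would be
  consistently enriched by construction.  Without the near-duplicate
  the construction keeps all pairwise Jaccard indices below the
  redundancy threshold (asserted at generation time).
- **Reference profiles.** Statistic = signal + Gaussian noise (signal
  3, noise sd 1).  `mimic` gives shared-up genes positive signal and
  shared-down genes negative signal (a treatment-like profile);
  `reverse` is its exact negation under the same seed (a
  tumor-vs-normal-like profile); `null` is pure noise.

What the generator does **not** model: read-level data, GC/length
biases, batch effects, isoform structure, gene-wise dispersion trends,
correlated genes.  Passing tests therefore demonstrate correctness of
the statistical machinery and recovery under the stated NB conditions —
not performance on real libraries, where dispersion heterogeneity and
correlation will lower power and inflate redundancy.

## Determinism and numerics

The pipeline is a pure function of (inputs, configuration, master
seed): stage seeds are spawned from one `numpy` `SeedSequence`, and all
ties anywhere break by ascending gene identifier.  Two runs with the
same configuration write byte-identical numeric outputs.  Numerical
guards: dispersion floor `1e-8`, pseudocount 0.5 in fold changes,
p-value floors `1/(B+1)` in every resampling test, equal hit steps when
all member statistics are exactly zero in the running sum.

## Problem sizes used in the checks

The bundled acceptance checks run the default study scale (13,716 genes,
4 contrasts, triplicates, 1000 permutations) once, plus null-calibration
batteries at 2,000 genes; exhaustive oracle comparisons cover all tag
placements with n <= 10, t <= 4 and all running-sum instances with
N <= 12, |set| <= 4, with larger randomized instances checked to 1e-12.
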
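# Methods

This note records the models implemented in `tandemapa`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open.

## Probe-level model of tandem-3'UTR APA

A tandem 3'UTR is a pair of isoforms sharing a 3'UTR start and ending at a
proximal vs a distal polyadenylation site. With `f` the long-isoform
fraction of a gene in a sample, probes upstream of the proximal site
("common" segment) measure total transcript abundance while probes in the
"extended" segment measure only the long isoform, i.e. on the log2 scale
an additive offset of `log2 f`. All coordinates are genomic, 0-based
half-open (BED); minus-strand tandems are stored with transcript-oriented
breakpoints (`utr_start > distal_end`) and probe order reversed
genomically.

### Structural filters

Transcripts sharing a gene, chromosome, strand and 3'UTR start with at
least two distinct ends yield one tandem candidate per shared start, using
the shortest end as proximal and the longest as distal (genes often have
more APA sites; the first functional site dominates observable isoform
shifts, so only one change point is modelled). Probes contained in more
than one candidate span are discarded entirely (unique mapping); a probe
straddling the proximal site joins the segment holding the majority of its
bases, ties going to the common segment (the annotation-silent case).
Tandems need ≥ 4 probes in each segment — fewer leave a segment mean too
poorly determined for change-point inference.

## Normalization

Intensities are assumed post-RMA log2 values. Two subtractive steps:

* **Transcript-median** (expression branch): per sample, subtract the
  median of the probes of each transcript, removing per-sample abundance.
* **Normal-median** (APA branch): per probe, subtract the median across
  the normal samples. Afterwards a normal-like sample is ~0 everywhere
  and a tumor's extended probes sit at `log2(f_tumor / f_normal)`. The
  singular "the normal sample" is read as the panel of normals; with one
  normal that sample's own row becomes zero, which is the correct
  degenerate reference. Reapplying the step is a no-op (normal medians
  are 0 after one pass), asserted in tests.

The APA branch uses the normal-median step only; the transcript-median
step serves the expression analyses. Raw CEL processing (RMA, quantile
normalization) is upstream of this package.

## Multivariate Bayesian change point

All `m` samples of a tandem are a multivariate series with a *common*
partition of the `n` probes into constant-mean blocks (product-partition /
Barry–Hartigan model). Per block and sample the mean is Gaussian around
the series mean with prior variance `σ²(1−w)/(w·k)` for a block of size
`k`; `w ∈ (0, w0]` is the signal-to-noise weight and the change
probability per boundary is `p ∈ (0, p0]`, both with uniform priors.
Integrating block means, each series' grand mean, the shared noise
variance (Jeffreys prior) and then `p` and `w` gives the partition
posterior

    P(ρ | X) ∝ ∫₀^p0 p^(b−1)(1−p)^(n−b) dp ·
               ∫₀^w0 w^(m(b−1)/2) (W + wB)^(−m(n−1)/2) dw

with `b` blocks and `W`, `B` the within-/between-block sums of squares
pooled over samples. A Gibbs sweep updates each boundary indicator from
the conditional odds of the two partitions that differ only at that
boundary; `rho_j` is the fraction of retained sweeps with a change at
boundary `j`, and the posterior probe means are the sweep-average of
within-block means per sample.

Defaults: `p0 = w0 = 0.2`, 50 burn-in + 500 retained sweeps — the
conventional defaults of product-partition change-point samplers; at the
planted-break conditions used in the tests these reproduce the exhaustive
single-change-point conjugate posterior argmax in ≥ 95% of instances while
keeping a 300-tandem profile under a minute.

Numerics: the `p` integral is an incomplete beta (scipy `betainc`, log
space); the `w` integral uses 32-point Gauss–Legendre quadrature on
`(0, w0]` with log-sum-exp, stable for exponents up to `m(n−1)/2` in the
hundreds. Block statistics come from cumulative sums, and the running
between-block sum is recomputed once per sweep to bound float drift. A
constant matrix (total SS ~ 0) short-circuits to the prior rate
`rho = p0/2` everywhere. Fewer than 8 probes yields `TOO_FEW_PROBES`
without sampling. Ties in `argmax rho` resolve to the smallest boundary.

### QC

* `MULTI_PEAK`: more than one local maximum of `rho` reaching 50% of the
  global maximum, maxima ≥ 2 boundaries apart — the signature of a second
  functional APA site. Plateaus collapse to their first index.
* `UNSTABLE`: averaged over samples, the within-segment standard
  deviation of the posterior means exceeds 0.5× the absolute
  between-segment mean difference in either segment. Segments that are
  numerically flat (sd below 1e−9 of the posterior-mean scale) are stable
  regardless of the (tiny) step, which keeps exactly-null noiseless
  tandems from being flagged on float dust.

Both rules replace a manual curation step; the two thresholds (peak
fraction 0.5, stability ratio 0.5) are the package's calibration of that
judgment.

### SUI

`SUI_i = w̄_ic − w̄_ie`, the difference between sample `i`'s posterior
segment means. The difference form (rather than a ratio) is isolated in
one function (`_sui_from_segment_means`) so it can be substituted; it is
the only form that makes SUI of a normal-median-normalized normal sample
0 and makes SUI equal `log2(f0/f)` for a planted fraction shift, which the
recovery tests exploit. Z-scores use the sample (n−1) standard deviation;
zero-spread tandems are flagged and their z-scores set missing.

## Differential APA

Per-tandem two-group comparison with empirical-Bayes variance moderation:
sample variances are modelled as scaled-F around a common `s0²` with `d0`
prior degrees of freedom, estimated by moment-matching the log variances
(bias-corrected with digamma/trigamma; `d0 = ∞` when the observed spread
of log variances does not exceed the chi-square expectation, giving a
common-variance test). The moderated `t` uses
`s̃² = (d0·s0² + d·s²)/(d0 + d)` with `d0 + d` degrees of freedom; `d0`
can be pinned to 0 (ordinary pooled t) or ∞ for the limit checks.
BH adjustment is step-up with monotonicity (statsmodels). Events are
reported as shortened/lengthened at `|ΔSUI| ≥ 0.2` and `q ≤ 0.05`; the
ΔSUI threshold applies at reporting only.

CV feature selection uses `|sd/mean|` with sample sd; a mean of exactly 0
maps to infinite CV (the tandem is maximally variable relative to its
center), and exactly `floor(0.25·n)` tandems are kept with ties broken by
id. IQR summaries use linear-interpolation (type-7) quantiles for
bit-reproducibility. SUI–expression association is Pearson per gene with a
seeded 2-component Gaussian mixture (10 restarts) summarizing the
bimodality of the correlation distribution.

## Subtyping

SUI profiles are min-max scaled per feature to [0, 1] (NMF needs
nonnegativity; min-max preserves each tandem's sample ordering and
relative spacing). nsNMF factorizes `X ≈ W S H`,
`S = (1−θ)I + (θ/k)·J`, θ = 0.5, by multiplicative KL updates with `S`
absorbed into `W` when updating `H` and vice versa; the divergence is
non-increasing per update (asserted on the logged trace) and runs stop at
a relative improvement below 1e−6 (checked every 10 iterations, cap 2000).
Multiple seeded random restarts keep the lowest-divergence run; the
consensus matrix is the run-average connectivity of argmax-`H` labels.
The survey/final restart counts (default 50 / 200) follow the convention
of reading the cited workflow's "iterations" as restarts; the inner
iteration cap is separate.

Rank selection surveys ranks 2–10: cophenetic coefficient (Pearson
correlation between `1−C` and the cophenetic distances of its
average-linkage dendrogram), dispersion (`mean 4(C−½)²`) and the mean
silhouette of consensus-derived labels under distance `1−C`. The selected
rank maximizes silhouette, ties resolving to the larger cophenetic
coefficient and then the smaller rank (most parsimonious equally-stable
solution) — on planted-k data the metrics saturate at the true k and the
parsimony rule prevents drifting to k+1.

Consensus k-means resamples 80% of samples without replacement 1000
times, runs seeded k-means++ and reports co-clustering over co-sampling;
never co-sampled pairs are imputed at 0.5 (maximal uncertainty) with a
warning. Final labels for both methods are exposed: argmax of `H` and the
average-linkage cut of `1−C`.

PCA coordinates are feature-centered SVD scores with the sign fixed so
each component's largest-|loading| feature is positive.

### Nearest shrunken centroids

Standard PAM training: `d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))`,
`m_k = sqrt(1/n_k − 1/n)`, fudge `s0 = median(s_i)`, soft-thresholded by
Δ; Δ is chosen by stratified cross-validated error (default 10 folds,
capped at the smallest class), ties to the largest Δ. Classification
uses `δ_k(x) = Σ (x_i − x̄'_ik)²/(s_i+s0)² − 2 log π_k` after quantile
normalization of new columns onto the training pooled quantiles
(mean-of-sorted-values reference; ties receive the mean of the tied
reference values).

## Screen statistics

Counts-per-million per (day, replicate); enrichment
`log2((cpm_d + 1)/(cpm_0 + 1))` per hairpin and replicate, averaged over a
gene's hairpins and replicates for the gene score. Depletion: one-sided
Mann–Whitney of a gene's pooled day-21 values against the control
hairpins' values (exact tail when both groups ≤ 10 values and untied),
BH over genes. Diversity shift: two-sample KS on log10 cpm. Replicate
concordance: Spearman with mid-rank ties. All statistics are
deterministic functions of the count table.

A caveat the tests quantify: every gene is compared against the *same*
control values, so the 23 tests are strongly positively correlated. BH
still controls the FDR, but the *expected count* of null genes at
q < 0.25 is ≈ 1.6–2 (bursts occur when the few control values land high
by chance), as the null-simulation test and the acceptance script
measure. With more control hairpins this coupling shrinks; with 3
controls it is intrinsic to the procedure.

## Synthetic data

The probe generator draws
`y_ps = β_p + a_ts + [p ∈ extended]·log2(f_ts) + ε`, with probe
affinities `β_p ~ N(0, 0.5²)`, per-sample abundances `a_ts ~ N(0, 0.5²)`
and noise `ε ~ N(0, σ²)`, σ = 0.25 by default — Gaussian log2-scale noise
is the standard model for RMA-processed intensities. Normals sit exactly
at the baseline fraction `f0` (default 0.8) so their true SUI is 0 by
construction; tumor subtypes scale `f0` by `2^effect`, clipped to (0, 1],
with effects that would push `f` above 1 rejected. Default cohort shape
mirrors a paired study: 33 normals, tumor subtypes of 36/36/67/26, six
probes per segment, and disjoint subtype signature blocks of −1 log2
(shortening) covering 25% of tandems.

The screen generator plants per-hairpin growth rates (−`depletion_rate`
log2/week for depleted genes, 0 otherwise including controls) and draws
multinomial counts at fixed library size (5e6) per replicate and day —
multinomial rather than Poisson so sequencing depth is exact, matching
the column-sum invariant. Defaults mirror a 95-hairpin pool: 23 genes × 4
hairpins + 3 non-targeting controls, days 0/7/14/21, 2 replicates.

What the generators do **not** emulate: probe cross-hybridization and GC
effects, correlated tandem co-regulation, partial isoform shifts within a
subtype, batch structure, PCR jackpotting and infection bottlenecks in
the screen. Passing recovery tests therefore demonstrates correctness of
the inference under the stated model, not robustness to those artifacts.

## Problem sizes and determinism

Recovery experiments run at: 200 oracle-comparison instances (n ≤ 12,
m ≤ 4), 300 planted-break tandems (4+4 probes, 40 samples, effect 1 log2,
σ = 0.25), a 200-tandem × 60-sample subtype recovery (4 × 15 samples,
survey with 8 restarts/rank across 10 seeds), a 2000-tandem null for test
calibration, and 20/50-seed screen batteries. These sizes were chosen so
the full battery completes in minutes on one CPU while leaving the checked
proportions' binomial error well below the asserted margins.

A single global seed fans out to per-stage child seeds via a SHA-256
counter hash (`stage_seed`), so each stage is independently reproducible;
all samplers use numpy `default_rng`. Identical config + seed gives
byte-identical outputs, asserted in tests.

## Known limitations

* One change point per tandem: tandems with several strong APA sites are
  excluded by QC rather than modelled.
* The moderated test supports the two-group design only.
* The SUI's published functional form is implemented as the difference of
  posterior segment means; any alternative (ratio, weighted combination)
  can be swapped in one function.
* Subtype counts below ~10 samples make the consensus metrics noisy; the
  rank survey is only validated for planted k ∈ {3, 4, 5}.
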
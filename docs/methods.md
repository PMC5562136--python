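# Methods

## The analysis problem

The pipeline contrasts bulk RNA-seq expression between the two EF1A
genotype classes of *Pisaster ochraceus* — *wild* homozygotes and *ins*
heterozygotes (the insertion allele is homozygous lethal, so only two
classes exist) — in a design with five individuals per genotype, each
sequenced at ambient temperature and after eight days at +3 °C.  Beyond
the genotype and temperature contrasts themselves, the pipeline asks how
robust the genotype partition is to label reassignment, and how much one
anomalous library (a wild-genotyped individual with ins-like expression,
plausibly a recombinant at the marker) drives the result.

## Count model and differential expression

Counts are modeled as negative binomial with variance `mu + phi * mu^2`
(`phi` is the dispersion; `sqrt(phi)` is the biological coefficient of
variation).  The two-class test is the classic conditional recipe:

1. **TMM normalization.**  Per-library factors are the weighted trimmed
   mean of per-fragment log2 ratios against a reference library (30% trim
   on M, 5% on A, inverse delta-method weights, factors rescaled to
   geometric mean 1).  The reference is the library whose upper-quartile
   CPM is closest to the mean upper-quartile.
2. **Expression filter.**  Fragments with CPM strictly above 1 in at
   least two libraries are kept; CPM uses raw library sizes because the
   filter runs before normalization.
3. **Quantile adjustment.**  Counts are mapped to a common effective
   library size (the geometric mean) through matched NB quantiles — a
   blend of normal and gamma quantile transforms, which keeps
   pseudo-counts continuous.  Group means come from a one-group NB fit
   per fragment at the working dispersion.
4. **Dispersion estimation.**  The common dispersion maximizes the summed
   conditional NB log-likelihood (the likelihood of counts given their
   group totals, valid once library sizes are equalized), searched on
   `phi in [1e-6, 10]` in log scale.  One alternation round is used:
   equalize at `phi = 0.01`, estimate, re-equalize, re-estimate, stop —
   bounded and deterministic.  Tagwise dispersions maximize
   `l_g(phi) + W * lbar(phi)` with `lbar` the mean conditional
   log-likelihood across fragments and `W = prior_df / residual_df`
   (prior_df 10, residual_df `sum_k (n_k - 1)`); maximization is a
   25-point log-grid search refined by quadratic interpolation.
5. **Exact test.**  Given the rounded pseudo-count group sums `z_A, z_B`
   with total `Z`, the null conditional law of `z_A` is
   beta-binomial(`Z`, `n_A/phi`, `n_B/phi`) (both groups share the
   per-library mean, so the NB success probabilities coincide and the
   conditional distribution is closed-form).  The two-sided p-value sums
   the probabilities of all outcomes no more likely than the observed
   one.  For totals up to 600 the pmf is evaluated by exact prefix sums
   of logs (stable at near-Poisson dispersions); above that, the
   more-likely-than-observed window is bracketed by bisection on the
   log-concave pmf and only the smaller of window/tails is enumerated, so
   small p-values are summed directly and never suffer cancellation.
   `logFC = log2(((z_B+0.5)/n_B) / ((z_A+0.5)/n_A))`; `logCPM` is the
   log2 mean pseudo-CPM with prior count 0.25.  Fragments with `Z = 0`
   report `p = 1, logFC = 0`.
6. **FDR.**  Benjamini–Hochberg step-up per contrast, never pooled across
   contrasts.

Orientation: class A = wild, class B = ins everywhere, so positive logFC
means higher expression in heterozygotes; `positive_class="wild"` flips
signs for display.

**Paired test.**  The paired treatment analysis fits, per fragment, an NB
log-linear model `log mu = log(effective size) + individual + treatment`
by vectorized IRLS at fixed tagwise dispersion, with step-halving to keep
the deviance monotone; p-values come from the likelihood-ratio statistic
against the no-treatment model (chi-square, 1 df).  Non-converged
fragments are flagged and report `p = 1`.

## Permutation robustness tests

The statistic is the number of fragments with FDR < alpha (default 0.01)
under the **full** two-class pipeline — normalization and dispersions are
recomputed inside every permutation, because "repeating the contrast"
means repeating all of it.  The *sorted* test enumerates all single moves
(2n partitions, classes become 6-vs-4), reciprocal single swaps (n^2) and
reciprocal double swaps (C(n,2)^2) of the observed genotype partition —
135 partitions for the 5-vs-5 design.  The *unsorted* test draws K random
equal-size splits (default 500), duplicates permitted across draws.

The reported percentile is the strictly-less fraction: ties count as
non-exceeding, matching the framing in which only partitions with
*higher* DE counts are "exceeding".  Because the DE-count statistic is
integer-valued and heavily tied near zero under the null, the strict
percentile cannot be uniform; the result therefore also carries a
randomized-PIT percentile (`pit`), the standard discrete-distribution
randomization `100 * (L + U*(T+1)) / (K+1)` with `L` strictly-less and
`T` tied permutations, which is exactly uniform under exchangeability and
is what the calibration battery tests for uniformity.

## Influence diagnostics

`influence_analysis` reruns the genotype contrast with one library
excluded, or with its genotype label flipped (reassignment detaches the
library from its individual so metadata invariants hold).  With a genuine
outlier, exclusion sharpens the contrast (more DE than observed) and
reassignment sharpens it at least as much — the qualitative signature the
diagnostics look for.

## Synthetic data generator

The generator emulates the study design: 2 genotypes x 5 individuals x 2
paired treatments = 20 libraries.  Fragment baseline abundances are
log-normal (sd 1.0 in log space); library sizes are log-normal; counts
are NB draws with per-fragment dispersions `phi0 * lognormal(0, sd)`.
Planted structure, all multiplicative:

- a fraction `pi_de` (default 0.02) of fragments carries a genotype
  effect of magnitude |log2FC| = 2, with fraction `rho` = 0.85 *lower*
  in heterozygotes (the direction asymmetry the analysis must recover);
- `k_wild` = 46 and `k_ins` = 6 temperature responders per genotype
  (the 46:6 ratio of the study design), magnitude 2, with 61% / 43%
  of responders down-shifted so the two genotypes' mean logFC have
  opposite signs;
- optionally one wild-labelled individual whose genotype-effect
  fragments follow 0.85 of the ins log-effect in both its libraries (the
  recombinant mimic).  The strength is a free parameter: full mimicry at
  desk scale collapses the observed DE count so far that permutations
  not involving the outlier also beat it, destroying the qualitative
  pattern the mimic exists to reproduce.

Default depth is lognormal(log 2e5, 0.15) at G = 2000 fragments — the
study's ~10M mapped reads over ~110k gene regions, scaled proportionally
to the default fragment count.  Default `phi0` = 0.15 (BCV ≈ 0.39,
typical for unrelated wild-caught animals) with lognormal spread 0.4.
One global seed expands into per-stage substreams, so regenerating one
output does not shift the others.

What the generator does **not** emulate: assembly artifacts and
multi-mapping, GC/length biases, library-preparation batch effects,
correlated expression modules, and individual-level random effects on
non-planted fragments.  Passing calibration here shows the machinery is
correct and well calibrated under the stated model, not that real
libraries meet those assumptions.

The righting-response generator draws log-normal trial times (three
trials in each of three periods) with wild times `ratio` (default 1.8)
times the ins times, individual-level noise, and occasional >1 h trials
to exercise the unresponsiveness rule.

## Behavioral comparison

Individuals with any trial above 3600 s are excluded entirely; summaries
are per-individual min/mean/sd per period and overall.  The genotype
comparison is a Welch two-sample t-test on per-individual values
(the safer default where only "t-test" is specified), with the ratio
defined wild/ins so 1.8 means heterozygotes right 1.8x faster.  A
label-permutation test on genotype means is provided as the
distribution-free alternative to a mixed-effects model fit, which is out
of scope.

## Calibration battery and problem sizes

`stardiff.calibration` regenerates every check from a seed: exact-test
agreement with 40-digit brute-force enumeration (200 instances, Z <= 200)
and with the exact binomial test in the Poisson limit; null calibration
(50 effect-free seeds at G = 2000: at most one false fragment in >=95% of
seeds — the occasional single false call at extreme shrinkage is a
property of weighted-likelihood methods, reproduced identically by an
independent reference implementation on the same data — and KS-uniform
randomized PITs from K = 20 unsorted permutations); common-dispersion
recovery within +/-25% at phi = 0.2; tagwise-vs-ML MSE over 20 seeds;
the outlier study over 20 seeds at G = 1000 with proportionally reduced
depth (the sorted test runs the full pipeline 136 times per seed, so the
fragment count is halved purely for tractability); direction-asymmetry
recovery over 20 seeds at default conditions; and the righting ratio over
20 seeds at the study size.

## Numerical choices

- Dispersion search bounds [1e-6, 10]; bounded Brent on log-phi,
  xatol 1e-4.
- Exact-test tie tolerance: outcomes within `exp(1e-10)` of the observed
  probability count as ties and are included in the p-value.
- IRLS: up to 50 iterations, 12 step-halvings, ridge 1e-8 on the normal
  equations; quantile-map probabilities that underflow fall back to
  mean-ratio scaling.
- Collapse output order is first-appearance order of group ids; ids that
  are already at the target level map to themselves (idempotence).
- Welch test with both group variances zero and equal means reports
  t = 0, p = 1 rather than NaN.

## Known limitations

- The exact test rounds pseudo-count group sums to integers; at very low
  counts the test is conservative (inherent to exact conditional tests).
- The paired LRT relies on the chi-square approximation; with 5+5
  individuals it is mildly conservative at alpha = 0.05.
- Tagwise shrinkage can produce a rare extreme false positive when true
  dispersions are heterogeneous (see the calibration note above).
- The homology collapse requires a pre-built feature map; building one
  from alignments is out of scope.
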
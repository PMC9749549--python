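# Methods

## The problem

Genomic selection predicts the genetic merit of individuals from
genome-wide marker genotypes. Parametric predictors built on an additive
kinship — GBLUP foremost — perform well when the trait architecture is
additive, but an additive relationship matrix is blind to epistatic
(locus-by-locus interaction) variance. Kernel learners such as
epsilon-insensitive support vector regression (SVR) with a radial-basis
kernel can absorb interaction signal but tend to give away accuracy on
purely additive traits. `gsblend` implements a simple, principled
combination of the two.

## The integrated predictor

Given predictions `Y_GBLUP` and `Y_SVR` for the same individuals, the
blended prediction is the convex combination

```
Y_Est = w * Y_GBLUP + (1 - w) * Y_SVR,
w     = s2_SVR / (s2_GBLUP + s2_SVR),
```

where `s2_GBLUP` and `s2_SVR` are the two models' error variances. This `w`
minimizes the variance of the combination under the idealization that the
two error processes are unbiased and uncorrelated; substituting it back
gives the blend's theoretical error variance

```
s2_Est = s2_GBLUP * s2_SVR / (s2_GBLUP + s2_SVR),
```

the "parallel resistor" form, strictly smaller than either component
variance whenever both are positive. The identity
`s2_Est = w^2 s2_GBLUP + (1-w)^2 s2_SVR` is property-tested. In practice
the component errors are positively correlated (both models see the same
training data), so `s2_Est` is an optimistic bound rather than an achieved
variance; the repeated-holdout evaluation measures what the blend actually
delivers.

Degenerate input: if both estimated variances are exactly zero the weight
is undefined; `integrate()` falls back to `w = 1/2`, which is inert because
two perfect predictors agree.

## Error-variance estimation: RCV and k-RCV

The weights require error variances estimated without touching validation
data. Refitted cross-validation (RCV) splits the training data into two
halves, fits on one half, scores the mean squared prediction residual on
the other, and averages the two directions. k-RCV partitions into k folds
(default k = 5), fits on each fold's complement, scores on the fold, and
averages the k per-fold mean squared residuals.

The original RCV for sparse high-dimensional regression refits a selected
submodel by ordinary least squares and divides by `n/2 - |S|` degrees of
freedom. GBLUP and kernel SVR have no discrete selected set and their
effective degrees of freedom are ambiguous, so this package uses the plain
held-out mean squared residual with the fold-size denominator. That choice
is biased upward by the predictor's own estimation error — conservative,
and harmless for weighting because both models are scored the same way on
*identical partitions* (the partition is a deterministic function of
`(n, seed, method, k)` shared across models).

Known-truth simulations (an oracle predictor with unit residual noise)
recover the noise variance within the Monte-Carlo band at n = 400–500, and
k = 2 k-RCV reduces exactly to two-half RCV on a shared partition.

## GBLUP engine

* **GRM** — VanRaden method 1: `G = W W' / (2 Σ p_k (1 - p_k))` with `W`
  the column-centered dose matrix and `p_k` estimated from the data;
  monomorphic markers are dropped; a `1e-6` diagonal ridge guarantees
  invertibility.
* **Variance components** — REML, profiled over the ratio
  `delta = s2_e / s2_g` on the eigenbasis of the GRM and minimized by
  bounded 1-D search on `log(delta)` over `[-12, 12]`. Deterministic, no
  starting-value sensitivity; a boundary optimum is returned with a
  warning. A constant phenotype collapses to `s2_g = 0`.
* **BLUE/BLUP** — Henderson's block system solved directly; the solution is
  verified against the relative residual (`<= 1e-8`) and, in tests, against
  a generic numeric maximizer of the joint log-density of `(y, m)`.
* **Prediction of new individuals** — conditional expectation through a
  joint train+test GRM: `g_test = G[te,tr] G[tr,tr]^{-1} m_hat`, with the
  training-block BLUPs re-solved on the joint GRM so both factors share one
  relationship scale. This is algebraically ridge regression on centered
  marker dosages with penalty `s2_e / s2_m`, `s2_m = s2_g / (2 Σ p q)`; the
  equivalence is tested at r > 0.999.
* Fixed effects default to an intercept; arbitrary design matrices are
  accepted through `MixedModelSpec`.

## SVR engine

Epsilon-insensitive L1-loss SVR, radial-basis kernel by default (bandwidth
`gamma = 1/p` on standardized markers), `c = 1`, `epsilon = 0.1`, marker
columns standardized to zero mean and unit variance. The RBF default is
deliberate: its feature space contains marker products, which is the whole
point of pairing a nonparametric learner with GBLUP; the linear kernel is
selectable for comparison. The quadratic program is solved by
scikit-learn's `SVR`; the module stores the dual coefficients, bias, and
standardization so prediction is an explicit kernel expansion, and a
linear-kernel fit exposes its primal weights for consistency checks. No
hyperparameter tuning loop is built in: defaults are fixed once and exposed
in `SVRConfig`.

## F2 simulator

Validation data come from a two-locus-orthogonal (Cockerham) QTL model on a
simulated F2 intercross.

* **Meiosis** — each individual is two independent gametes; a gamete's
  parental phase starts Bernoulli(1/2) at the first marker and switches
  between markers with the Haldane recombination fraction
  `r = (1 - exp(-2d/100))/2` for map distance `d` cM; no crossover
  interference; chromosomes independent. Doses 0/1/2 count one parent's
  alleles, so every locus segregates 1:2:1 in expectation.
* **Contrasts** — additive `x = dose - 1`, dominance `z = 1/2 - |dose - 1|`.
  These are orthogonal with mean zero under 1:2:1 frequencies (tested).
* **Genetic values** — `G = mu + Σ a x + Σ d z + Σ (i_aa x1 x2 + i_ad x1 z2
  + i_da z1 x2 + i_dd z1 z2)`.
* **Phenotypes** — `Y = G + e`, `e ~ N(0, Var(G) (1 - h2) / h2)`, so the
  broad-sense heritability `Var(G)/Var(Y)` matches the target; the realized
  sample ratio is reported and converges to the target (within 0.03 at
  n = 2000).

Default scenario dimensions: 200 individuals, 10 chromosomes × 200
equispaced SNPs on 100 cM (marker spacing 0.5 cM), h² ∈ {0.3, 0.5, 0.7}.
Architectures: `a_e0` places one additive QTL (|a| = 1, sign alternating by
chromosome) at the middle marker of each chromosome; `a_e1`/`a_e2`/`a_e3`
place two QTL at the 1/3 and 2/3 markers of the first 5/7/10 chromosomes,
each pair interacting within-chromosome with `i_aa = 1` (other interaction
classes zero by default) and each QTL carrying an additive effect of
magnitude 1, the remaining chromosomes empty. Chromosome length in cM, QTL
effect magnitudes, dominance effects, and the active interaction classes
are not canonical — they are config fields with the defaults above, chosen
as round, conventional values for mixed additive+epistatic architectures.
`mu` defaults to 0.

What the simulator does *not* emulate: missing genotypes or phenotypes,
genotyping error, multi-allelic markers, population structure or family
stratification, linkage disequilibrium beyond what meiosis on a uniform map
induces, and crossover interference. Passing tests therefore demonstrate
correctness of the machinery and the claimed qualitative orderings under a
clean F2 design, not performance on structured breeding panels — real-data
robustness must be assessed on real data (the readers accept dose 0/1/2 and
presence/absence 0/1 tables for exactly that purpose).

## Evaluation protocol

Repeated random 70/30 train/validation splits (100 repetitions by default;
reduced-scale runs use 20). Per repetition: both component models are
fitted on the training split; the variance pair is estimated by RCV or
k-RCV *within the training split only* (no validation leakage); the weight
is formed; all three predictors are scored on the validation split by
predictive ability (Pearson r between observed and predicted phenotype) and
mean squared error. Aggregates are the mean and the standard error
`sd/sqrt(reps)` across repetitions. Per-repetition seeds derive
deterministically from the base seed, so a run is bit-reproducible.
Repetitions with a constant train or validation phenotype (Pearson r
undefined) are excluded and counted rather than crashing.

Metrics are computed on the validation split — the standard genomic
selection practice — and an intrinsic consequence is the accuracy ceiling:
the expected correlation between a genotype-based prediction and the
*phenotype* cannot exceed `sqrt(h2)`. Desk-scale runs here respect that
ceiling (asserted in tests), which is why published absolute predictive
abilities above it are treated as qualitative orderings, not numeric
targets.

## Numerical and design choices

* GRM ridge `1e-6`; fitted variances floored at `1e-8` before entering the
  Henderson system.
* REML search bounds `log(delta) in [-12, 12]`, `xatol = 1e-8`.
* SVR QP tolerance `1e-6`, unlimited iterations; constant-phenotype fits
  degrade to a bias-only predictor with a warning.
* Phenotype files are written with 6 significant digits; genotypes as
  integers; marker positions in cM; loci in truth files are 1-based.
* Problem sizes in the test suite and acceptance script (20-repetition and
  10-repetition holdouts, 50–70-individual oracle instances, 5–20 seeds for
  calibration) are reduced-scale choices that keep the full validation run
  in seconds while leaving the Monte-Carlo bands well inside the asserted
  tolerances.

## Known limitations

* The inverse-variance weight ignores the covariance between the two
  models' errors; with strongly correlated errors the blend's realized gain
  over the better component is small (and is only asserted to be "at par or
  better" within 0.05 in validation).
* RCV variances are upward-biased for slowly-learning predictors (half the
  data is a harsher fit than 70%), most visibly for SVR with fixed
  hyperparameters.
* REML uses a single genetic variance component; dominance or epistatic
  kinships are out of scope.
* The SVR hyperparameters are not tuned per dataset; predictive ability of
  the SVR arm on real data will generally benefit from tuning that this
  package intentionally leaves outside its scope.
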
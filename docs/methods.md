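# Methods

## Scope and data model

The package analyses two kinds of input. Genotype tables hold per-variant
base calls (A/C/G/T) for a panel of inbred mouse strains with 1-based
genomic coordinates; heterozygous ("H") and no-call ("N") entries become
cell-level missing values rather than dropping the variant, since inbred
strains are expected homozygous and a variant remains classifiable from
its remaining strains. Expression tables hold per-measurement
allele-specific readings for F1 hybrid females: a maternal-allele fraction
(pyrosequencing) or a maternal/paternal read-count pair (RNA-seq). Count
pairs are converted to fractions at load using the posterior mean under a
Jeffreys Beta(1/2, 1/2) prior, (m + 0.5)/(m + p + 1); a beta-binomial
observation layer was considered and rejected as the default because the
rest of the pipeline, like the assays themselves, operates on ratios.
Internally all coordinates are 1-based inclusive (the convention in which
interval boundaries are printed in the mouse literature); BED output
converts to 0-based half-open.

## SDP classification and interval scan

A variant's strain distribution pattern (SDP) codes each strain 0 when it
shares the reference strain's (C57BL/6J) allele and 1 otherwise. Because
the coding is anchored to the reference strain, classification is *not*
symmetric under relabeling of the phenotype groups: group 0 is the
reference strain's phenotype group (Xce^b in the classical panel), group 1
the alternative (Xce^a). The three-way rule is:

* consistent — every non-missing group-1 strain is 1 AND every non-missing
  group-0 strain is 0;
* inconsistent — at least one group-1 strain is 0 AND at least one group-0
  strain is 1;
* partially consistent — everything else.

Two edge cases the rule text leaves open were resolved as follows.
Monomorphic (all-zero) SDPs classify by the literal rule as partially
consistent and carry an explicit flag so downstream filters can drop them.
An SDP whose phenotype group is entirely missing cannot be consistent
(the conservative reading); this choice preserves missingness
monotonicity — blanking a call can demote consistent or inconsistent to
partially consistent but never convert one into the other. Variants with
more than two observed alleles are excluded from classification, and
variants whose reference call is missing are skipped (they cannot be
polarized), both with counters.

The scan splits the position-sorted classified records at inconsistent
variants. Each inconsistent-free segment containing at least `min_count`
consistent variants (default 5 — the real candidate run is supported by
two orders of magnitude more, and the threshold keeps single-SNP runs from
winning) is a candidate run; partially consistent variants may sit inside.
The winning run has the most consistent variants, ties broken by longer
consistent span and then leftmost position, for determinism. The minimum
interval is the [first, last] consistent position of the winning run; the
maximum interval is open-bounded by the nearest flanking inconsistent
variants, falling back to the first/last classified variant. The
implementation is checked against an O(n²) brute-force best-segment search
on tables up to 500 variants.

Strain-addition refinement reclassifies every SDP over the enlarged panel
and reports boundary displacement in kb. Since the consistent rule is a
conjunction over strains, adding strains can only demote classifications;
the consistent set after refinement is provably a subset of the one
before, and a property test checks this on random tables.

## Hierarchical beta model

Measurements are first mapped to a single canonical scale: the fraction of
expression attributable to the *focal* strain's active X (if the focal
strain is the dam, the maternal fraction; else its complement). One scale
avoids maternal/paternal double bookkeeping; parental orientation is
metadata used only by the parent-of-origin test. Fractions are clamped to
[ε, 1−ε], ε = 0.005, before likelihood evaluation (pyrosequencing reports
whole-percent resolution, so exact 0/1 readings are boundary artifacts).

With Beta(mean m, precision t) meaning shapes (mt, (1−m)t) and variance
m(1−m)/(t+1):

    p_i  ~ Beta(mu_c(i), theta_c(i))          latent per-mouse proportion
    y_ij ~ Beta(m_ij, tau_j * lambda_c(i))    measurement layer
    logit(m_ij) = logit(p_i) + beta_j

mu_c is the cross-level mean XCI proportion, theta_c the between-mouse
precision, beta_j and tau_j the bias and precision of gene-tissue
combination j, and lambda_c a cross-specific multiplier on measurement
precision. Two modeling choices were genuinely open: the gene-tissue bias
enters additively on the log-odds of the measurement mean (keeping m_ij
inside (0,1) for any bias), and lambda_c multiplies the measurement-layer
precision rather than the individual-layer one (the minimal reading of
"cross-specific variance" in the measurement process; the alternative
placement is a one-line change).

Priors (all constants config-exposed through `PriorConfig`):

| parameter | prior | default |
|---|---|---|
| logit(mu_c) | Normal(0, sd) | sd = 1.5 |
| log(theta_c) | Normal(m_θ, s_θ²) | m_θ ~ N(log 30, 1), s_θ ~ half-N(1) |
| beta_j | Normal(0, s_β²) | s_β ~ half-N(0.5) |
| log(tau_j) | Normal(m_τ, s_τ²) | m_τ ~ N(log 30, 1), s_τ ~ half-N(1) |
| log(lambda_c) | Normal(0, sd) | sd = 0.5 |

Sampling is adaptive random-walk Metropolis within Gibbs on the
transformed (logit/log) scales. Blocks that are conditionally independent
(p_i across mice; beta_j, tau_j across gene-tissues; the per-cross
parameters across crosses) are updated elementwise in vectorized sweeps.
Normal-mean hyperparameters (m_θ, m_τ) use conjugate Gibbs draws;
half-normal scales use Metropolis on the log scale. Step sizes adapt by
Robbins-Monro toward 0.44 acceptance during burn-in only, so the
post-burn-in kernel is fixed and the chain valid. Defaults are 4 chains ×
10,000 iterations with 2,000 burn-in; the analysis scripts and acceptance
runs use 2 × 4,000 / 1,000, which on these data give split R-hat < 1.01.
Each chain's RNG derives from `SeedSequence([seed, chain])`, making runs
bit-reproducible; split R-hat and effective sample size come from arviz,
and a warning state is set when any R-hat exceeds 1.05. Posterior
summaries are equal-tailed (mean, median, central 95% interval from pooled
post-burn-in draws); highest-density intervals would be the other
defensible choice and differ negligibly for these unimodal posteriors.

### Allele calling

The tail probability of a cross is min(P(mu < 0.5), P(mu > 0.5)) estimated
from pooled draws, draws exactly at 0.5 splitting evenly. A partner allele
is excluded when every cross against a carrier of it has tail probability
below α_share (default 0.05, config-exposed; no published numeric cutoff
exists, the tails being used "like p-values"), with the direction recorded
(focal stronger when the posterior mean of the focal-active fraction
exceeds 0.5). Exactly one surviving allele is the call. If all partners
are excluded and the direction pattern is consistent with the series
a < e < b < c < d, a new allele is declared between the strongest partner
the focal beats and the weakest that beats it; contradictory directions,
replicate crosses that disagree, or two or more surviving alleles yield
"ambiguous". Because the tail probability behaves like a p-value, a true
allele-sharing cross is falsely excluded with probability near 2·α_share;
at the default threshold roughly one phenotyping experiment in ten ends
ambiguous or miscalled, which mirrors the inconclusive outcomes that occur
in practice.

## Parent-of-origin permutation test

Specimen-level estimates p̂_i default to the arithmetic mean of a mouse's
canonical fractions (transparent and assumption-light); the posterior mean
of p_i is available when a model fit exists. Mice are grouped by the
unordered pair of parental Xce alleles — aggregating genetic backgrounds —
keeping only unequal pairs whose alleles sit in the series order;
equal-allele reciprocal pairs are excluded from the headline statistic
(they address a separate question) but remain reportable. Orientation is
the parental origin of the *stronger* allele, and p̂ is placed on the
strong-allele-active scale (complemented when the stronger allele came
from the sire). Per-group delta is the strong-maternal minus
strong-paternal mean of p̂; the overall delta is the unweighted mean over
groups (group-size weighting is exposed as an option). The null shuffles
orientation labels independently within each group, preserving counts;
the p-value uses the add-one estimator (1 + #{|δ*| ≥ |δ|})/(1 + n_perm)
with n_perm = 10,000 by default, two-sided by default (sidedness is a
flag). An exhaustive enumeration over all within-group label assignments
serves as the oracle on small groups. Under the no-effect null the two
orientations are exactly exchangeable on the strong-allele scale (the
mirrored beta laws coincide), so the test is exact; a calibration test
confirms uniform p-values.

## Synthetic data

`simulate_genotypes` plants a perfectly phenotype-consistent haplotype
inside a chosen interval, forces variants onto both planted boundaries,
and draws outside SDPs as independent fair coins per strain, redrawing any
outside row that reproduces the phenotype pattern — so at zero noise the
scan recovers the planted interval with certainty, and every consistent
variant outside the interval is attributable to injected noise.
Discordance flips individual calls at a given rate, including the
reference strain's call (which repolarizes the whole row), so a planted
variant survives as consistent with probability (1−rate)^n_strains — the
binomial oracle used in tests. Missingness blanks calls independently.

`simulate_xci` draws from exactly the hierarchy the model assumes. Cross
means come from relative allele strengths, mu = w_m/(w_m + w_p), so equal
strengths give 0.5. The default strength map (a 1.0, e 1.25, b 1.55,
c 2.3, d 3.2) is a set of invented calibration constants chosen so that
heterozygote means fall in the 0.25–0.75 band observed across real Xce
heterozygotes; they are configuration, never estimates. The
parent-of-origin effect is injected as a log-odds shift (default 0.25 in
the analysis scripts, giving per-group deltas of roughly 5–10 percentage
points, the observed order of magnitude) applied only when the stronger
allele is maternal. Pyro mode rounds fractions to 3 decimals (instrument
resolution); RNA-seq mode draws maternal read counts Binomial(depth, m_ij)
at default depth 200. All randomness flows from one integer seed and
ground truth is serialized beside every dataset.

Because the generator and the model share the same hierarchy, parameter
recovery and coverage tests validate the *inference machinery*, not the
model's adequacy for real data: real assays have gene-specific biases that
drift between batches, counts are overdispersed relative to binomial, and
litters correlate mice within crosses. None of these features are
simulated, so passing tests bound algorithmic, not biological, error.

## Problem sizes and test design

Simulation-backed checks run at sizes chosen to keep the default test run
a few minutes long while leaving the checks well-powered: posterior
recovery at 40 mice × 15 gene-tissue measurements (posterior mean within
0.02 of truth); credible-interval coverage over 100 datasets of the same
size with single-chain fits (coverage must land in [0.90, 0.99] — the
sampler's measured frequentist coverage at this size is ≈ 0.96);
permutation-null uniformity over 20 replicates × 2,000 shuffles
(Kolmogorov–Smirnov p > 0.01) and power > 80% over 50 replicates at a 0.4
log-odds injected effect with 30 mice per orientation; the
homozygous-cross check over 40 replicates, which sits deliberately at the
calibration boundary (under perfect calibration exactly 90% of equal-
allele crosses have tail probability ≥ 0.05, and the model's mild
conservatism keeps it at or above that line). The focal-symmetry check
verifies that re-fitting on the complementary scale mirrors the posterior
mean to within Monte-Carlo error (0.01); the canonical-fraction and
label-swap symmetries are exact and asserted exactly.

## Known limitations

* The sampler is single-machine and dense; designs beyond a few thousand
  measurements would warrant blocked likelihood caching or compiled
  kernels.
* Allele calling assumes the partner panel brackets the focal strain;
  a focal allele outside the tested range yields "new_above"/"new_below"
  with no finer placement.
* The maximum candidate interval at chromosome ends falls back to the
  outermost classified variant rather than a true telomere coordinate.
* Secondary (selection-driven) XCI skewing, autosomal modifiers, litter
  effects and escape-gene artifacts are all out of scope.
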
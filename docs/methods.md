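# Methods

## The estimation model

A female heterozygous for an X-linked mutation is, after random X-chromosome
inactivation (XCI), a mosaic of cells expressing one X or the other. With a
GFP cassette linked to the normal allele, GFP-positive cells mark the
normal-allele-active lineage. The estimator rests on two assumptions:

1. the two lineages are produced in equal numbers early in development
   (random XCI, pre-elimination positive fraction *p* = 0.5), and
2. the GFP-positive (normal) lineage persists through the observed stages.

Then the positive fraction and the mutant-lineage survival probability are
linked by *P*<sub>GFP+</sub> = 1/(1 + *P*<sub>survival</sub>), inverted as
*P*<sub>survival</sub> = 1/*P*<sub>GFP+</sub> − 1. The transform is convex
and undefined at *P*<sub>GFP+</sub> = 0 (which would mean the *normal*
lineage vanished — an assumption violation the code reports as an error,
naming the animal).

### Aggregation order

Each animal's counts are pooled into one fraction, transformed, and the
group summary is the mean ± SEM of the per-animal survival estimates.
Transforming per animal and then averaging is not the same as transforming
the group-mean fraction (Jensen's inequality: the per-animal average is
larger), and it is the order consistent with "average of independent
experiments ± SEM" reporting and with published survival values computed
from strongly depleted tissues. Per-animal estimates above 1 (fractions
below 0.5) cannot arise from the generative model except through sampling
or counting noise; they are capped at 1 and counted in `clipped_n` so the
truncation is auditable.

### Uncertainty

Groups have 4–8 animals, so no distributional form is assumed: the CI is a
seeded percentile bootstrap over animals (B = 2000 by default). Two
small-sample refinements matter at n = 8:

- the bootstrap resamples the *untruncated* per-animal estimates and the
  resulting interval endpoints are then clipped into [0, 1]
  (bounded-parameter bootstrap). Resampling already-capped values truncates
  the upper tail of the bootstrap distribution and visibly undercovers when
  the true survival is near 1;
- the interval is read at expanded percentile levels
  Φ(−t<sub>n−1,1−α/2</sub>·√(n/(n−1))) rather than α/2 (Hesterberg's
  expanded percentile), correcting the systematic narrowness of the plain
  percentile interval at small n.

In the package's Monte-Carlo studies (200 replicates, 8 animals × 500
cells) the nominal 95% interval covers the true cumulative survival ~95% of
the time at s = 0.714 and ~92% with miscount correction at s = 0.8.

### Miscount correction

GFP counting over-counts positives (autofluorescence), modeled as one-way
misclassification: a truly negative cell is recorded positive with
probability α, so E[p<sub>obs</sub>] = p + α(1 − p). Given a known or
assumed α, the correction p = (p<sub>obs</sub> − α)/(1 − α) is applied per
animal before the transform; observations below α are infeasible under the
model and rejected. Raw (uncorrected) estimates are biased toward
elimination — with α = 0.05 and true survival 0.8 the raw mean estimate is
≈ 0.73. α is not estimable from a single fraction; it must come from
negative-control tissue or be treated as a sensitivity parameter.

## The cohort simulator

The generator produces the data structure the estimator assumes, plus
controlled violations of it:

- **Founder pool.** XCI is committed in a pool of `n_founders` progenitors,
  each keeping the reporter-bearing X active with probability
  `p_inactivate_mutant_x` (default 0.5). Per-animal variation in the
  pre-elimination fraction φ is binomial in the pool size.
- **Clone expansion.** Each region's tissue is built from the founders'
  clones with symmetric-Dirichlet relative sizes, concentration
  1/`clone_dispersion` (`0` = equal clones). Founder pool and dispersion
  jointly set the between-animal spread of the positive fraction.
  Defaults `n_founders = 200`, `clone_dispersion = 1.0` give a per-animal
  sd of ≈ 5.5 percentage points, i.e. a between-animal SEM of 1–2
  percentage points at n = 8 animals — the dispersion wild-type tissues
  show in this experimental setting. The founder count is an *effective*
  (per counted region) pool size calibrated to that dispersion, not a claim
  about progenitor biology.
- **Staged elimination.** Stages are an ordered label list; the first
  listed stage reflects only XCI and clone expansion, and the survival
  entry for stage *t* applies to the interval ending at *t* (the first
  entry defaults to 1; setting it below 1 encodes elimination completed
  before the first observation, e.g. Purkinje cells already ~100% positive
  at P6). Counts at each (region, stage) are binomial draws of
  `n_cells_per_region` cells from the current tissue fraction; the counted
  total is exactly the requested cell number.
- **Competition.** Optionally the mutant lineage's per-stage survival is
  penalized by the linear form s<sub>eff</sub> = s(1 − κ·φ<sub>high</sub>),
  with φ<sub>high</sub> the normal-lineage tissue fraction recomputed after
  each stage. The penalty applies to transitions into stage t ≥ 1 only (the
  first stage precedes elimination); it is inert in uniform mutant tissue
  (φ<sub>high</sub> = 0), which is what makes the hemizygote-vs-heterozygote
  contrast informative. The linear form is this package's one-parameter
  phenomenology — the biology motivates a competitive mechanism, not a law.
- **Randomness.** One root seed per cohort; each animal consumes a stream
  derived deterministically from (seed, animal index), so cohorts are
  reproducible and individual animals can be re-simulated in isolation.

What the generator does **not** emulate: spatial clone geometry and
neighborhoods (competition acts through tissue-level fractions only),
counting-window selection effects, stage-to-stage animal identity (stages
are drawn independently, mimicking cross-sectional designs), false
*negatives* in counting, and any elimination of the reporter-positive
lineage. Passing recovery tests therefore show the estimator works when its
assumptions hold and degrades as modeled (miscounting, competition) — not
that real tissues satisfy those assumptions.

## Staged-hazard trajectory fit

The postnatal positivity trajectory f<sub>t</sub> = p/(p + (1 − p)
Π<sub>k≤t</sub> s<sub>k</sub>) is fitted for the per-stage survivals
s<sub>k</sub> ∈ [0, 1] by weighted least squares (weights 1/SEM² where the
SEM is positive, else 1), using L-BFGS-B with box constraints. Starts are a
stagewise closed-form inversion of the observed fractions plus a coarse
grid of constant vectors, making the fit deterministic; on noiseless input
the fitter returns the generating survivals to < 1e−6. A single stage is
rejected as underdetermined. Consistency-scale recovery checks in the test
suite run on simulated cohorts of 200 animals per stage: with the
calibrated between-animal dispersion, per-stage survival estimates at
realistic cohort sizes (n = 4–8) carry sampling sd of ≈ 0.05–0.08, so
±0.05 recovery statements are only meaningful at larger simulated n.

## Competition identification

Given a uniform-genotype (hemizygote-analog) reference survival
s<sub>uniform</sub> — from simulation truth or an external measurement such
as layer thickness; a single-genotype tissue's own reporter fraction is
uninformative — and a mosaic cohort, the coefficient is identified by
inverting the linear form:

κ̂ = (1 − s<sub>mosaic</sub>/s<sub>uniform</sub>) / φ̄<sub>high</sub>,

with s<sub>mosaic</sub> the capped per-animal survival at the final stage
and φ̄<sub>high</sub> the observed positive fraction averaged over stages
and animals. Averaging over stages includes the near-pre-elimination first
stage and is less downward-biased than using the adult (post-elimination)
fraction alone; because φ rises as elimination proceeds, κ̂ still carries a
small conservative (downward) bias — in the package's paired-design study
(κ = 0.4, s = 0.8, two stages) the mean κ̂ is ≈ 0.36 and the bootstrap 95%
CI covers the truth in ≈ 90% of replicates. The stage at which competition
acts is not identifiable from endpoint fractions; the penalty is applied at
every post-XCI transition by convention. κ̂ is reported raw
(`kappa_raw_`, used for bias assessment — a [0,1]-clipped estimator cannot
average to zero under the null) and clipped (`kappa_`). Layer thickness is
modeled as proportional to the surviving tissue fraction
φ + (1 − φ)·s with a between-animal measurement CV (default 7.5%,
matching reported thickness SEMs at n = 7); note the mosaic layer is
thinner than the uniform one only when κ·φ·s > 1 − s, i.e. competition
strong relative to the cell-autonomous deficit.

## Statistics protocol

Two-group comparisons run a Shapiro–Wilk normality check per group
(recorded and warned on failure, never blocking), then a two-sided
Student's t-test assuming equal variances (a Welch flag is exposed), with
asterisk tiers ns / * / ** / *** at 0.05 / 0.01 / 0.001 (half-open at the
boundaries). Zero-variance pairs: equal means give statistic 0, p = 1;
unequal means give an infinite statistic, p = 0. Percentages in written
outputs are rounded to one decimal place; no multiple-testing correction is
applied, matching the reporting convention the protocol mirrors.

## Numerical and design choices

- Probabilities validated to [0, 1] at construction; configs are frozen
  dataclasses, errors are typed (`xcimosaic.errors`).
- Survival transform raises on a zero fraction rather than returning inf;
  ingestion rejects zero-denominator records with the offending line.
- Optimizer tolerances: ftol 1e−14, gtol 1e−12, ≤ 500 iterations per start.
- Bootstrap seeds: one `SeedSequence` per estimator, spawned per group in
  sorted group order, so group results do not depend on table row order.
- Recovery-study sizes (200 replicates of 8 animals × 500 cells; 200
  animals for trajectory consistency) are the package's chosen simulation
  scales; they complete in seconds.

## Known limitations

- XCI skew *p* and survival are not jointly identifiable from a single
  fraction; *p* is a supplied parameter (0.5 by default).
- The miscount rate α must be externally supplied.
- The linear competition form is phenomenological; κ̂ is defined only
  relative to it, and its inversion is mildly conservative.
- Stages are a discrete time base; no continuous-time hazard or apoptosis
  mechanism is modeled.
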
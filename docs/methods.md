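# Methods

## Detection model

For one taxon, one sampling method and one season, detections across
sampling units are pooled: every unit shares a single standardized
detection probability `p60` (per 60 L of filtered stream water, or per 60
camera-trap days). A unit with effort `e_j` (litres or trap-days) detects
the taxon with probability

    π_j = 1 − (1 − p60)^(e_j / 60).

This complementary-log-log scaling is the unique memoryless choice: the
probability of *missing* a taxon factorizes over sub-samples, so two
independent 30 L samples miss exactly as often as one 60 L sample. It is
also the form implied by quoting "detection probability per 60 L" for
surveys whose actual volumes ranged from ~25 to ~80 L (filtration sometimes
ended early when filters clogged). Camera surveys use season-level
detection (y = 1 if the taxon was ever photographed at a site) with
trap-days as effort under the same scaling; no day-level histories are
needed.

The likelihood is independent Bernoulli(π_j); the prior on `p60` is
Beta(1, 1) (configurable). Assumptions worth stating plainly: no
site-level occupancy/detection separation (all units are exchangeable
draws for the taxon), no spatial or temporal correlation between units,
and replicate water samples at a site are independent trials.

### Posterior computation

Two engines, validated against each other:

- **Grid posterior** (`posterior_grid`) — trapezoid quadrature of the
  unnormalized posterior on a uniform grid over [0, 1], 4001 points by
  default. With all efforts equal to 60 this reproduces the conjugate
  Beta(1+k, 1+n−k) posterior; with mixed efforts it is exact up to grid
  resolution (a 10^6-point grid moves the mean by < 10⁻³). Deterministic,
  so it is both the default production engine and the oracle for the
  sampler.
- **Random-walk Metropolis** (`sample_posterior`) — on θ = logit(p60),
  with the Jacobian p(1−p) in the target. Defaults: 3 chains × 20,000
  iterations, 5,000 burn-in. The proposal scale starts at 0.8 and is
  adapted toward ~44% acceptance during burn-in only (Robbins–Monro on the
  log scale, updated every 50 iterations), then frozen, so the retained
  draws come from a fixed-kernel chain; without adaptation the fixed scale
  mixes poorly on near-boundary posteriors from small surveys. Summaries
  are bit-reproducible given the seed.

All-zero and all-one detection histories are legal; the posterior simply
concentrates near the boundary (and the uniform prior keeps estimates off
it: zero detections in 50 equal-effort samples give mean 1/52).

## MOTU filtering

Fixed order: (1) delete every MOTU present in a negative control; (2) drop
MOTUs whose best reference-database similarity is strictly below 0.96,
except whitelisted ones (the whitelist generalizes curated inclusions of
taxa whose only reference sequence is a close congener); (3) assign each
MOTU a reporting rank — species if its candidates name one species, genus
if they span one genus, subfamily if one subfamily, excluded with a warning
otherwise; (4) zero any per-sample count whose fraction of the taxon's
total reads *within its sequencing library* is below 0.001, with totals
computed once on the input, not iteratively re-derived as cells are zeroed;
(5) binarize summed per-taxon counts to 1/0 per sample, with effort = the
sample's volume.

The tag-jump denominator ("per taxon and per library") is read as the
taxon's library-wide read total; the alternative reading (per sample within
library) would make the rule scale with sequencing depth per sample rather
than with the taxon's leak source, which is the artifact being filtered.
The chain is idempotent on its own output, non-increasing in reads and
MOTUs at every step, and its final binarization is invariant to rescaling
all counts by a positive constant.

## Covariate GLMs and model selection

Poisson log-link (richness per sample) and Bernoulli logit-link
(per-taxon × sample detection) models are fit by IRLS to
max |Δβ| < 10⁻⁸ (cap 100 iterations), with exact log-likelihoods (the
Poisson keeps the −log y! term so AICc values are comparable across
implementations) and covariance from the inverse Fisher information.
Rank-deficient designs are rejected naming the collinear columns;
quasi-separation (|β| > 30 in a logistic fit) flags the fit
non-convergent rather than returning divergent estimates.

Model selection enumerates every additive subset of the candidate
covariates (factors enter/leave as blocks; the null model is included) and
ranks by AICc; subsets within ΔAICc < 2 form the equivalence set.
Defaults mirror the study's two candidate sets: {log catchment area,
volume, rain the previous day, year-as-factor} for richness, plus
{catchment-average camera detection rate, diet, log body mass} for
detection. Treatment coding uses carnivore as the diet reference and the
earlier year as the year reference; body mass is log-transformed because it
spans four orders of magnitude (voles to moose). Volume enters as an
ordinary covariate in the GLM (additive treatment), not as an offset — the
GLM layer is deliberately agnostic of the cloglog standardization used by
the Bayesian layer. Predictions carry delta-method standard errors
(SE(μ) = |dμ/dη|·SE(η)); detection curves are evaluated at 60 L, a 500 km²
catchment, and rain ∈ {0, 30} mm over a grid of camera rates.

## Diversity and cost-efficiency

Turnover is the additive beta-diversity fraction `(γ − ᾱ)/γ`, reported to
two decimals (richness means to one decimal, costs to whole dollars).
Accumulation curves are a true bootstrap: each of 1000 iterations draws a
full with-replacement sequence of sampling units and accumulates union
richness over its prefixes — marginally, effort m is m uniform draws with
replacement, and the curve is non-decreasing within every iteration, so
the Monte-Carlo mean is monotone by construction. Intervals are 2.5/97.5
percentiles. Cost curves re-index the bootstrap means by m × per-unit cost.

Per-unit costs divide a survey's total cost by its number of samples or
camera sites, rounding half-up to the dollar. When a cost table carries an
explicit total that disagrees with the sum of its printed components by
more than $1 (the shipped table does, for three of four rows), the explicit
total wins and a warning is logged; published tables occasionally include
line items not broken out into components, and the per-unit figures follow
from the totals.

## Synthetic landscape

The generator emulates the assumed generative process so every stage runs
against known truth:

- **Community** — taxa are assigned to higher taxonomic groups (bears,
  canids, felids, ungulates, lagomorphs, small mammals, bats, other) with
  fixed proportions; each group fixes a diet and camera-detectability.
  True `p60` is Beta-distributed per diet: carnivore Beta(2, 6) (mean
  0.25), omnivore Beta(3.5, 4.5), herbivore Beta(4, 4.5) — encoding the
  food-chain expectation that top predators deposit less DNA in streams.
  Daily camera rates λ are log-normal (σ = 0.6) with median
  0.1 × p60/(1 − p60): both detection odds and camera activity proxy local
  abundance, which is what makes camera rates informative about eDNA
  detection in the fitted models.
- **eDNA surveys** — detections are Bernoulli with the same cloglog effort
  scaling the estimator assumes; rain and log-catchment-area effects
  (defaults 0.02/mm and 0.15 per log(km²/100)) shift the cloglog-scale
  probability. Because the fitted covariate model is binomial-logit, it is
  a deliberate mild misspecification of this truth — mirroring the
  separation between the Bayesian standardization and the logistic
  covariate modelling in the analysis protocol.
- **Scenario presets** — `paper_2018` (50 spatial samples of 30 L across 42
  sites) and `paper_2019` (36 catchment samples cycling 75/55/30 L from 2
  sites) encode the two study designs.
- **Camera surveys** — independent detections per site-day are
  Poisson(λ_t), aggregated to picture totals and detection-days.
- **MOTU tables** — detected cells receive gamma-Poisson
  (negative-binomial-like) read counts; contaminant MOTUs flagged in
  negative controls, low-similarity MOTUs, and per-library tag-jump leaks
  (Poisson with rate 10⁻⁴ of the taxon's library total) are layered on so
  the filter chain has real work to do.

What the generator does **not** emulate — and therefore what passing tests
do not establish about field data: site-level heterogeneity in camera rates
(one λ per taxon everywhere, so synthetic camera turnover is far lower than
in real surveys), DNA transport, decay and dilution dynamics, seasonal diet
shifts, imperfect taxonomic reference databases, and PCR/sequencing
stochasticity beyond the count noise described above.

## Numerical choices and degenerate inputs

- Grid posterior endpoints: a uniform prior contributes exactly zero at
  p ∈ {0, 1} (the 0 × (−∞) case is handled explicitly), so boundary mass
  is only limited by grid resolution.
- Likelihoods return −∞, not an exception, when a zero-probability event
  is observed.
- IRLS starts the Poisson intercept at log(mean response) to avoid
  overflow; linear predictors are clipped at ±30 before exponentiation.
- AICc is undefined for n ≤ k + 1; such candidates stay in the selection
  table with missing AICc rather than disappearing silently.
- Empty MOTU tables, all-control tables, never-detected taxa, and
  single-unit accumulation curves are all legal degenerate inputs with
  warnings where appropriate.
- Child seeds for pipeline stages derive from the root seed via
  `SeedSequence`, keeping every stage independently reproducible.

## Problem sizes

The analysis scripts and tests run at the study's own design sizes (50 and
36 water samples, 57 cameras) with a 40-taxon community; statistical
property checks use 200 replicates (parameter recovery, subset recovery),
50 random designs (IRLS oracle agreement), 20 datasets (sampler-vs-grid),
and 1000 bootstrap iterations, matching the published resampling effort.
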
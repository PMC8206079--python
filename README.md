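# streamdna

Tools for comparing **stream-water eDNA metabarcoding** with **camera
trapping** as terrestrial-mammal monitoring methods: effort-standardized
Bayesian detection probabilities, covariate GLMs with AICc all-subsets
selection, MOTU read-table filtering, diversity turnover, and bootstrap
cost-efficiency curves — exercised end-to-end on a synthetic landscape with
known ground truth.

## The problem

Stream networks act as conveyor belts for DNA shed by the terrestrial
animals of their catchments. Filtering stream water and metabarcoding a 12S
mitochondrial marker can reveal which mammals use a landscape, but a fair
comparison with camera trapping requires putting both methods on a common
effort scale and accounting for sampling covariates (water volume,
rainfall, catchment size) and species ecology (diet, body mass).

## The model

Each taxon, method and year gets one pooled detection probability `p60` —
the probability of detection in a standardized unit of effort (60 L of
filtered water, or 60 camera-trap days). Heterogeneous effort enters
through the memoryless complementary-log-log scaling

    π_j = 1 − (1 − p60)^(e_j / 60)

so that splitting a 60 L sample into two independent 30 L samples leaves
the probability of missing the taxon unchanged. Detections are independent
Bernoulli(π_j) across sampling units, the prior is Beta(1, 1), and the
posterior is computed two ways — a deterministic grid quadrature and a
random-walk Metropolis sampler on logit(p60) — each serving as the other's
check.

Around the detection model sit: the MOTU filter chain (negative-control
removal → 96% reference-similarity filter → species/genus/subfamily
assignment → per-taxon per-library 0.001 tag-jump filter → 1/0
binarization); from-scratch IRLS GLMs (Poisson log-link for per-sample
richness, binomial logit-link for per-taxon detection) ranked by
`AICc = −2 logL + 2k + 2k(k+1)/(n−k−1)` over every additive covariate
subset; turnover `(γ − ᾱ)/γ`; 1000-iteration bootstrap
species-accumulation curves; and richness-per-dollar curves built from the
published survey cost table.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
landscape (each writes its tables under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_filter_motus.py
python analysis/03_estimate_detection.py
python analysis/04_fit_models.py
python analysis/05_diversity_cost.py
python analysis/06_compare.py
```

Script 03 prints, for the simulated 36-sample catchment survey:

```
130 estimates written
catchment 2019 vs survey-average truth: mean |error| 0.052, 95% CI coverage 0.95
```

i.e. the pooled posterior means recover the survey-average per-60 L
detection probabilities to ~0.05 with nominal interval coverage. Script 05
prints the diversity/cost summaries, e.g.

```
edna_catchment_2019: gamma=40, alpha=19.9, turnover=0.5; reaching 32 taxa costs $1,704
camera_2019:         gamma=25, alpha=23.3, turnover=0.07; reaching 20 taxa costs $455
```

— `gamma` is total richness, `alpha` the mean per-unit richness, turnover
the fraction of total richness an average single unit misses, and the cost
figures come from multiplying the bootstrap effort needed by the per-unit
survey cost. The same chain is available as one call:
`streamdna.pipeline.run_all(PipelineConfig(out_dir=...))`.

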
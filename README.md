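# paceshape

Pace-and-shape analysis of demographic senescence in duckweed cohorts.

Duckweeds (*Lemna* spp.) are tiny floating plants whose ramets ("fronds")
bud off daughters daily for a few weeks and then stop. Because a frond's
physiological death is hard to score visually, death is defined
*operationally* as the day its final daughter detaches, and a cohort
experiment reduces to a long table of per-frond daily offspring counts.
`paceshape` turns such tables — real or simulated — into the standard
comparative-senescence analysis:

- **Parametric mortality models.** Exponential (constant hazard, the
  no-senescence reference), Weibull (μ = *ab*x*ᵇ*⁻¹), Gompertz
  (μ = *a*e^{bx}) and logistic (μ = *a*e^{bx} / (1 + (*as*/*b*)(e^{bx}−1)),
  a Gompertz hazard decelerating to a plateau) are fitted to lifespans by
  maximum likelihood — exact event times or day-interval censoring — and
  ranked by AICc = −2 ln L + 2k + 2k(k+1)/(n−k−1).
- **Pace and shape.** Pace is mean reproductive lifespan. Mortality shape
  is 1 − CV of lifespan, computed per species-block cohort cell: 0 under
  constant hazard, →1 when everyone dies at the same age, negative when
  mortality declines with age. Fecundity shape is a per-individual OLS
  slope of mean-standardized fecundity on pace-standardized age, from
  first to last reproduction.
- **Marginal reproduction model.** The daily probability of reproducing
  is modeled as logit P(y=1 | age) = β₀ + β₁·age by GEE with each frond a
  cluster, an AR(1) working correlation (days immediately after a
  reproduction are less likely to see another), and robust sandwich
  standard errors.
- **Trait comparisons.** Two-way ANOVAs (Species, Block, interaction;
  sequential SS) for lifespan, mortality shape, total offspring,
  fecundity shape and two frond-size traits, with Tukey–Kramer all-pairs
  tests and compact letter displays.
- **Cohort simulator.** A first-class generator of synthetic cohorts with
  the same structure: parametric latent death days (pace-scaled per
  block), latency-delayed logit-linear daily reproduction with Markov
  lag-1 serial correlation, rare two-daughter days, truncation at last
  reproduction, and a small post hoc loss rate.

## Worked example

Simulate the default three-species, four-block design (444 fronds) and run
every stage:

```sh
paceshape run-all --seed 1 --mode interval --out demo/
```

or equivalently from Python:

```python
from paceshape import RunConfig, paper_like_config, run_all

report = run_all(RunConfig(sim_config=paper_like_config(seed=1),
                           likelihood_mode="interval",
                           out_dir="demo", seed=1))
```

which prints (from `demo/summary.txt`):

```
paceshape run (seed 1)

cohort: 444 fronds, 15 excluded

best mortality model by species (dAICc of runner-up):
  LG: weibull (next model dAICc 5.97)
  LM: logistic (next model dAICc 2.46)
  LT: weibull (next model dAICc 0.74)

pace and mortality shape (species pooled):
  LG: mean lifespan 26.4 d, shape 0.746 (n=147)
  LM: mean lifespan 26.6 d, shape 0.707 (n=141)
  LT: mean lifespan 25.9 d, shape 0.732 (n=141)

GEE reproduction probability (first -> last modeled age):
  LG: 0.524 -> 0.163 (slope -0.0444, alpha -0.093)
  LM: 0.552 -> 0.254 (slope -0.0279, alpha -0.072)
  LT: 0.540 -> 0.388 (slope -0.0143, alpha -0.099)

trait comparisons (Species p; Tukey letters):
  log(lifespan): p=0.8127; -
  shape_mortality: p=0.1128; -
  total_offspring: p=5.147e-09; LG=b LM=a LT=a
  shape_fecundity: p=5.043e-06; LG=b LM=a LT=a
  log(surface_area): p=3.802e-188; LG=a LM=b LT=c
  log(perimeter): p=1.731e-174; LG=a LM=b LT=c
```

Reading this: the three species live ~25–27 days on average with strongly
age-increasing mortality (shape ≈ 0.7–0.75, far from the constant-hazard
value 0); the exponential model loses by hundreds of AICc units while the
age-dependent families are separated by only a few. Daily reproduction
starts near 0.52–0.55 and declines with age, fastest for LG — so LG also
has the steepest (most negative) fecundity-shape slopes and its own Tukey
letter for that trait, and the three species separate cleanly on size.

Every stage is also available separately (`simulate`, `fit-mortality`,
`pace-shape`, `gee`, `anova`) on long-format cohort CSVs with columns
`frond_id, species, block, age_day, offspring_count` (optional per-frond
`excluded, exclusion_reason, surface_area, perimeter`).

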
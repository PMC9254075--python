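# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `paceshape`.

## Data model and the operational definition of death

The demographic individual is a frond (ramet). Age is counted in whole
days; age 1 is the first full day after the frond detached from its
parent. A frond's record is its vector of daily daughter counts, and its
death day is *defined* as the day of its final reproduction — a
retroactive, operational convention forced by the fact that physiological
death of a duckweed frond cannot be scored reliably by eye. Two
consequences propagate through the package:

- an included frond's record always ends in a positive count (the reader
  trims trailing zero days, and validation rejects records that end in 0);
- a frond that never reproduces has no death day under this definition and
  is flagged `excluded` with reason `no_reproduction`. The source
  experiments never describe such fronds; the flag is this package's
  convention for completeness.

Counts are integers, not booleans: total reproductive output counts a
two-daughter day as 2, while the marginal reproduction model binarizes.

## Mortality models and fitting

Four standard demographic hazards are implemented (see the table in
`mortality.py`). The logistic family uses the three-parameter (a, b, s)
form whose s → 0 limit is Gompertz and whose Gompertz b → 0 limit is
exponential, so maximized log-likelihoods are nested:
logistic ≥ Gompertz ≥ exponential, and Weibull ≥ exponential (b = 1).

Numerics. The logistic integrated hazard is computed as
H = log1p(s·G)/s with G the Gompertz integrated hazard; this is exact for
all s ≥ 0 and, via `log1p`, remains accurate as s → 0. (A truncated series
in s is *not* used: it diverges when s·G² is large and can fabricate
infinite likelihoods.) G itself uses `expm1` and a b → 0 guard.

Two likelihood modes are offered for daily-censused lifespans:

- `exact` (default): the density evaluated at the recorded day,
  Σ [log μ(tᵢ) − H(tᵢ)];
- `interval`: death on day t is an event in (t−1, t],
  Σ log(S(tᵢ−1) − S(tᵢ)).

For genuinely day-censused data the interval likelihood is the correctly
specified one (for the exponential model it is exactly the geometric pmf).
The exact mode applied to day-rounded data systematically rewards hazards
with a delayed onset — the rounded exponential looks like a *shifted*
exponential density on the integers — which inflates the apparent support
for age-dependent models. Model-comparison studies in the test suite
therefore use interval mode; exact remains the default for continuity with
common practice when event times are treated as known.

Likelihood evaluation aggregates lifespans by distinct value with
multiplicity weights (identical sums, far fewer hazard evaluations, since
daily lifespans repeat heavily).

Optimization is multi-start Nelder-Mead over unconstrained coordinates
(log-transformed positive parameters; the rate b raw). Defaults: 20 seeded
starts, fatol 1e-8, xatol 1e-7, ≤1200 iterations. Each model additionally
starts at its nested predecessor's reduction (and, in `compare_models`, at
the predecessor's *fitted* parameters), which enforces the nesting
hierarchy up to optimizer tolerance. The exponential/exact MLE is the
closed form n/Σt. Fits report `converged`; model comparison ranks by AICc
among converged fits only, breaking exact ties toward fewer parameters.
Zero-mass observations return −∞ rather than raising, so the optimizer can
back out of bad regions.

## Pace and shape

Pace = mean reproductive lifespan. Mortality shape = 1 − SD/mean of
lifespan, with the n−1 sample SD (the source material does not specify the
denominator; n−1 is standard practice). It is a cohort-level statistic —
an individual dies once — computed per species-block cell (12 cells in the
default 3×4 design) and species-pooled.

Fecundity shape is the per-frond OLS slope of y on x over the window from
first to last reproduction, where x = age / (mean lifespan of the frond's
species-block cell, computed over all included fronds before any
shape-related exclusions) and y = daily count / (total offspring /
lifespan). Zero-count days inside the window contribute y = 0. Fronds
whose window is a single day have no slope; they are recorded with
`defined = False` and dropped from downstream ANOVAs with a logged count.
Both shapes are invariant to rescaling time (and counts), which the test
suite asserts — shape is decoupled from pace by construction.

## Marginal reproduction model

Per species, each included frond is a cluster of binary daily outcomes
y(age) = [count ≥ 1] for ages `omit_first_days`+1 .. death_age (default
omits the first 2 days: all species show a reproduction latency). The
marginal model logit P(y=1) = β₀ + β₁·age is estimated by GEE (statsmodels
engine: binomial family, Fisher-scoring GEE updates, robust sandwich
covariance) with AR(1) working correlation over a cluster's ordered
observation days; exchangeable and independence structures are available
options, and independence reproduces ordinary logistic-regression point
estimates (asserted against the GLM path). With complete daily records the
observation-index lag and the age lag coincide, so the AR(1) parameter α
is the day-to-day residual correlation. Predictions are
expit(β₀ + β₁·age); non-converged fits refuse to predict.

## The cohort simulator

The generator emulates a randomized-block cohort experiment and is the
test bed for every downstream stage. Per frond:

1. a latent physiological death day is drawn by inverse-transform sampling
   from the species' survivorship with the time axis stretched by the
   block's pace multiplier, rounded up to the daily census grid (every
   death day ≥ 1);
2. daily reproduction after a latency (default 2 days) follows marginal
   probabilities expit(β₀ + β₁·age) with lag-1 serial correlation α
   induced by a two-state Markov chain that preserves the marginals
   (transitions falling outside [0,1] are clipped with a logged warning);
   a reproducing day yields 2 daughters with a small probability;
3. the record is truncated at the last reproduction day (the operational
   death), which shortens recorded lifespans slightly relative to the
   latent law, exactly as the real protocol does; never-reproducing fronds
   are excluded as `no_reproduction`;
4. independent post hoc loss (default 3%) marks fronds `simulated_loss`,
   emulating contamination/clumping losses.

Default design (`paper_like_config`): 3 species × 4 blocks × 37 fronds
(initial n = 444). Species use logistic mortality with (b, s) chosen for
strongly age-increasing, decelerating hazards and a solved by bisection so
the *operational* mean lifespans land near 27, 26.5 and 25 days — the
reported magnitudes for *L. gibba*, *L. minor* and *L. turionifera* under
lab conditions. Reproduction intercepts/slopes are the logit lines through
the reported endpoint probabilities (≈0.55–0.58 at age 3, declining to
0.07–0.19 at each species' maximum age), giving the slope ordering
LG steepest < LM < LT. Serial correlation defaults to −0.1 (fronds are
*less* likely to reproduce the day after reproducing); twin probability
0.02. Block pace multipliers 0.90/0.95/1.02/1.13 emulate the shelf
temperature gradient (warm blocks live faster); they scale pace only —
shape-varying block effects are out of scope. Per-species log-normal frond
sizes (means 12/7/3.5 mm², CV 0.2; perimeter ≈ 4√area with 5% noise)
provide the two size traits with the observed ordering LT < LM < LG.

What the simulator does *not* emulate: mechanistic temperature or resource
dependence, parental-age effects (the real design removed them), genet
(colony) dynamics, day-to-day environmental shocks shared within a block,
and any link between frond size and demography. Passing tests therefore
certify the statistical machinery under the stated generating process, not
the biology of any particular dataset.

## Trait comparisons

Six responses: log(lifespan), cell-level mortality shape, total offspring,
fecundity shape, log(surface area), log(perimeter) — natural logs, applied
where the untransformed data are heteroscedastic/non-normal in the source
design. ANOVAs use sequential (Type I) sums of squares with Species
entered first, then Block, then the interaction (a Type II switch is
provided; with the near-balanced default design the difference is small).
The mortality-shape ANOVA has one value per cell and hence no interaction
term (df: Species 2, Block 3, Residual 6, Total 11). Significant Species
effects (α = 0.05) trigger Tukey–Kramer all-pairs tests using the two-way
model's MSE and residual df, q = |mᵢ−mⱼ| / √(MSE/2·(1/nᵢ+1/nⱼ)) referred
to the studentized range (equal-n reduces to Tukey HSD, asserted against
statsmodels), summarized by an insert-and-absorb compact letter display.
No multiplicity correction is applied across the six responses.

## Pipeline and reproducibility

`run_all` executes simulate/ingest → mortality comparison per species →
pace/shape tables → per-species GEE → trait ANOVAs, writing TSV/JSON
outputs rounded to 6 significant digits, a manifest (seed, config hash,
versions) sufficient to re-execute the run, and a human-readable summary.
All randomness flows from a single root seed; identical configs produce
byte-identical outputs (asserted).

## Problem sizes used in the checks

The automated checks run at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances while remaining quick: grid-refinement MLE
oracles at n = 50; model-selection studies at 50 replicate samples of
n = 2000; GEE recovery at 20 replicates of 500 clusters; the ANOVA null
(type-I error) at 100 replicate 3×4×12 cohorts; large-sample shape
identities at 10⁵ draws.

## Known limitations

- The mortality stage has no right-censoring (every frond is followed to
  operational death); the interval option is the only censoring handled.
- Gini- and entropy-based shape measures are not implemented (they are
  known to correlate strongly with the CV-based measure on empirical
  data).
- The GEE working-correlation α is estimated by the statsmodels
  least-squares moment scheme; with sparse within-cluster gaps an
  age-lag-aware estimator could differ, but default cohorts have complete
  daily records.
- Cell mean lifespans for pace standardization use each species-block
  cell; pooled curves use pooled means. Other standardization choices are
  possible and would shift fecundity-shape values slightly.
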
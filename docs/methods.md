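# Methods

## Generative model

One session is four dictator blocks of 12 trials. Each block's dictator
has a static character, so within a block the learner is a recursive
Bayesian filter with identity state transitions.

**States.** The classify-refine family uses a 2 × 2 grid over harmful
intent × self-interest with attribute levels 0.05 ("beneficial") and
0.95 ("detrimental"). The classic family uses a 6 × 6 grid at the bin
midpoints {1/12, 3/12, …, 11/12}. States are enumerated HI-major.

**Priors over states.** The HI marginal has central tendency `pHI0` with
prior evidence `dEv·EvRat`; the SI marginal has `pSI0` with evidence
`dEv`; the joint prior is their outer product. With two levels a marginal
is fully determined by its mean, `(1−p, p)`, so in the classify-refine
family `dEv` and `EvRat` only shape the classic family's discretised-Beta
prior (Beta with the given mean and concentration, evaluated at the grid
values and normalised). `dEv` is therefore inert in the two-state
likelihood — it is carried for vocabulary compatibility with the classic
family, and fits simply return it near its prior mode.

**Policies and likelihood refinement.** State *s* maps to a fair-split
probability σ(w0 − wH·HI(s) − wS·SI(s)). The classic family pins
p(outcome|s) at these values. The classify-refine family holds them as
Dirichlet pseudo-counts: `counts(s, fair) = aEv·p(fair|s)`,
`counts(s, unfair) = aEv·(1−p(fair|s))`. Per trial:

1. Bayes step: posterior ∝ prior × row-normalised counts for the
   observed outcome;
2. credit step: `counts(s, outcome) += posterior(s)`
   (posterior-weighted credit assignment);
3. forgetting: `counts ← baseline + ω·(counts − baseline)`, i.e. an
   exponential decay of the learned excess toward the initial counts,
   applied once per trial after the credit step;
4. the posterior becomes the next trial's prior.

Between dictators, the learned excess carries over at rate `λ_other`
(`next counts = baseline + λ_other·(end counts − baseline)`), while state
beliefs reset to the initial prior: a new dictator's character is
unknown, but what "beneficial/detrimental" mean generalises. Carry-over
acts on likelihood counts only, not on state priors — blending the prior
means as well would confound the initial-belief parameters (`pHI0`,
`pSI0`) with the generalisation mechanism. The classic family, having no
counts, neither forgets nor carries over; `aEv`, `ω` and `λ_other` are
fixed (inert) in its model specifications, which is why `classic-full`
has 8 free parameters.

**Report channels.** Each of the three reports is a draw from a
discretised softmax over an 11-bin scale (0, 0.1, …, 1):
p(bin) ∝ exp(−alphaPrec·(bin − value)²). The expectation report is scored
against the pre-outcome predictive Σ prior(s)·p̂(fair|s); the HI and SI
reports against the posterior mass on the detrimental state of each
dimension (classic: the posterior-expected attribute value). For nonwhite
dictators both attribution values — not the expectation — are shifted by
`POCbias` on the log-odds scale before scoring. A single precision is
shared across channels. Observed reports are snapped to the nearest bin.
The squared-distance kernel is one of several reasonable channel choices;
it is isolated in one function so an alternative (e.g. a log-score
kernel) can be swapped in.

## Fitting

MAP estimation maximises log-likelihood plus independent weakly
informative priors defined in native space: Beta(1.2, 1.2) on `pHI0`,
`pSI0`, `ω`, `λ_other`; Gamma(shape 2, scale 2) on `dEv`, `EvRat`,
`alphaPrec`, `aEv`; Normal(0, 2²) on `wH`, `wS`, `w0`, `POCbias`. These
are broad re-specifications, overridable in one table
(`inference.py`). Optimisation is over transformed coordinates (logit /
log / identity; boundary clamp 10⁻¹²).

The optimizer is an adaptive multistart coordinate grid search: from the
prior mode plus seeded prior draws, each free dimension is scanned on 7
points spanning ± its radius (initially 2.0 transformed units), the best
point is adopted, and radii contract by 0.5 per sweep unless the best
move sat on the grid edge; it stops when every grid step is below 10⁻³ or
after 40 sweeps. Gradient-based optimisers are deliberately not the
primary fitter — these likelihood surfaces are multimodal. A Nelder–Mead
simplex then polishes the grid optimum (kept only if it improves): the
likelihood has diagonal ridges, most prominently between typing
confidence and retention, along which axis-aligned search stalls.
Channel probabilities are floored at 10⁻¹² before logs, and the channel
softmax is max-stabilised so extreme precisions cannot underflow.

Per-participant model scores use
BIC = k·ln(n) − 2·LL + 2k(k+1)/(n−k−1), with n counting every report
datapoint (144 for three channels, 96 for attribution-only fits) and the
small-sample (AICc-style) term applied to BIC; the uncorrected AIC is
emitted alongside. A parameter fitted once across the sample would
contribute ln(n_total)/(n_participants·ln(n_i)) equivalent parameter
units per participant, so its summed penalty is ln(n_total); the penalty
arithmetic is implemented (`model_space.effective_k`), though no default
model specification uses sample-shared parameters and the per-session
fitter does not estimate them jointly.

## Synthetic cohorts

The generator reproduces the study design: 74 participants, 42
randomised to citalopram, two waves with 66 completing follow-up, four
blocks per session (two 80%-fair, two 20%-fair dictators; apparent
ethnicity balanced two white / two nonwhite; block order randomised per
session), 12 Bernoulli outcomes per block, and reports drawn from the
model's own channel distributions.

Population parameters are Normal in transformed space. The default
means/spreads (in `synthetic_cohort.py`) were chosen once so that
simulated behaviour is non-degenerate and every learning parameter is
actually expressed in behaviour: moderate initial pessimism about harm
(pHI0 ≈ 0.30) and mild expected self-interest (pSI0 ≈ 0.60); positive
policy weights (wH = 2.0, wS = 1.5, w0 = 1.0) so predictives start in the
interior and refinement is required to reach the true 80%/20% rates;
typing confidence log-mean ln 2.5 (a few trials of prior evidence, sd
1.0); retention mean 0.60 (logit-sd 1.2), squarely in the range where
forgetting shapes within-block dynamics; and decision precision log-mean
ln 20, under which reports scatter one to two bins around the model value
— tight enough that learning dynamics remain visible, noisy enough that
single reports are unreliable. The drug effect enters as additive
transformed-space shifts at follow-up in the citalopram arm, by default
−1.18 on log typing confidence and +1.32 on logit prior self-interest. A
configurable outlier fraction draws from a widened population to exercise
the outlier screen (off by default).

What the generator does *not* emulate: real response granularity and
anchoring habits, within-session drift in precision or attention,
questionnaire-linked individual differences, and any misfit between the
model family and human learning. Passing recovery tests therefore shows
the pipeline is correct and the design is informative about these
parameters — not that human data will be equally well behaved.

## Recovery experiments and their limits

Parameter recovery simulates a 74-agent single-wave cohort, fits the
winning model (10 free parameters), and correlates generating with
recovered values in transformed space. Under the default conditions the
policy intercept (fairnessB) and decision precision recover with
r ≈ 0.9, typing confidence r ≈ 0.7, and retention r ≈ 0.5–0.6.
Retention is the weakest and the most variable across cohort draws
(roughly r ≈ 0.3–0.7): with 48 trials, `ω` and `aEv` trade off along a
likelihood ridge — both control how far the outcome likelihoods refine —
and for agents with ω near 1 the data genuinely prefer
wrong-but-equivalent solutions (their fitted posteriors exceed the
generating ones). This mirrors the empirical finding that retention is
individually stable but with the lowest explained variance of the stable
parameters, and is a real identifiability limit of the 4 × 12 design, not
an optimizer artefact.

Model recovery simulates cohorts from each family, fits both the winning
classify-refine and the classic model to every session, and selects the
family with the lower median BIC per cohort. Family assignment is
essentially perfect even with a deliberately light optimizer budget,
because the families differ grossly in fit.

## Second-level statistics

Stability analyses regress follow-up values on baseline with drug,
gender and subjective-SES covariates, using Huber M-estimation (default
tuning constant) for the hypothesis test and the matching OLS adjusted R²
as the variance-explained summary. Before mixed-effects analyses, OLS
influence diagnostics flag points with Cook's distance > 1 or
|internally studentised residual| > 3 (both strict inequalities; a point
exactly on a threshold is kept); exclusion is per-analysis. Treatment
contrasts use value ~ wave·drug + (1 | participant) random-intercept
models (REML); p-values are Wald-based and reported uncorrected. In
calibration simulations at the study's size the interaction's type-I
error is close to, and slightly above, the nominal 5% (the band
0.025–0.08 at 500 replicates is used as "calibrated"), as expected for
Wald tests without small-sample degree-of-freedom corrections.

## Problem sizes and determinism

All experiments are reproducible bit-for-bit from their configuration
seeds; fitting is deterministic given the fit configuration. Default
suite and acceptance-script sizes are chosen to run on one CPU in a few
minutes: recovery at the full 74-agent study scale with a 3-start
optimizer; model recovery with 20 replicate 30-agent cohorts per family
in the test suite (8 replicate 20-agent cohorts in the acceptance
script) under a light 1-start optimizer budget, which the gross
family differences tolerate; 500-replicate null calibration for the
mixed model; and a 140-session two-wave cohort for the drug-effect
recovery.
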
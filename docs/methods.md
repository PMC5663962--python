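# Methods

This note documents the models and procedures implemented in `orphanbonds`,
the choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Data model

The pipeline consumes three tables. The **registry** carries one row per
individually known elephant: id, sex, birth year (fractional calendar years),
maternal link, core social group, optional death year, and — for males — a
natal-dispersal flag. **Follows** are timed focal observation bouts (at most
30 minutes, at most one per focal per activity per day) of non-parous females
aged 6–17, in one of two activities, feeding or resting, each recording the
set of conspecifics present in the aggregation. **Interactions** are single
events between the focal and one partner during a follow; only the six
affiliative types (bodily contact, trunk touch, greeting, allomothering,
play, trunk-to-mouth) enter the analysis, other types are retained but
filtered.

From these, the dyadic observation table is assembled per activity and
stratum (orphan / non-orphan): for focal *j* and partner *i*, the exposure
γ<sub>ij</sub> sums the durations of *j*'s follows in which *i* was present
and the count y<sub>ij</sub> tallies their affiliative events in those
follows. Aggregation membership is per-follow and binary: a partner recorded
present contributes the whole follow's duration to γ, since entry and exit
times within a bout are not recorded. Dyads that were never co-present are
excluded rather than zero-filled — without exposure there is no observation.
Partners of every age/sex class are candidate dyads; a partner fitting no
category simply carries all-false flags.

## Partner categories and covariates

Categories follow the field definitions: **age mate** (within ±2 years of
the focal), **aunt** (adult maternal aunt, where "adult" is taken as ≥ 18
years — one year past the focal sampling class, since no other boundary is
recorded), **bull** (male dispersed from his natal group), **calf** (at most
six months old at some point during the study window), **matriarch** (oldest
living female of the partner's core group at the study midpoint, excluding
the focal itself and the focal's mother), **mother**, and **sister**
(maternal). Flags are non-exclusive — a young maternal sister is both sister
and age mate — with the single structural exclusion that a mother is never
the matriarch. Grandmothers are not a category (too few alive in the study
population this design mirrors). Missing ancestry yields false kin flags and
a debug log entry rather than an error.

Ages are calendar-year differences; the focal's `age` covariate is her mean
age across the follows entering that model, and `age_orphaned` is her age at
her mother's death. Orphan status is evaluated at the end of the study
window, so a focal whose mother died mid-study is analyzed as an orphan.

The two continuous covariates are z-scored within stratum and activity at
design-matrix assembly. Whether to scale them was an open choice; scaling
puts their coefficients on a per-standard-deviation footing comparable with
the 0/1 category flags and keeps a single prior sensible for all
coefficients. A zero-variance continuous column is centered to zeros and its
coefficient is then informed by the prior alone (the fit warns about weak
identification).

## Descriptive layer

Per-category interaction rates are the per-dyad y/γ, summarized as median
and IQR over dyads in each (category, stratum, activity) cell; a dyad with
several true flags contributes to every matching cell, since the categories
are not exclusive. Empty cells are absent, not zero.

Group comparisons use the Kruskal–Wallis rank-sum statistic computed from
mid-ranks, H = 12/(N(N+1)) Σ R²_k/n_k − 3(N+1), divided by the tie
correction 1 − Σ(t³−t)/(N³−N); when every pooled value is identical the
correction vanishes and H is defined as 0. P-values come from the χ²
approximation with (groups − 1) degrees of freedom regardless of sample
size, matching the reporting convention of the analysis this package
implements; an exact two-group permutation p-value is available as an option
for very small samples. The per-focal statistics fed to these tests are
partners-per-minute (distinct affiliative partners over follow minutes;
focals with no minutes in the activity are excluded) and the mean
partner−focal age difference, either over all affiliative partners or
restricted to older female partners. Using per-focal means rather than
pooled per-partner values keeps focals as the independent replicates;
pooling would pseudo-replicate within focal.

Before any model is fit, all covariate pairs are screened for collinearity;
a pair with |Pearson r| strictly above 0.7 blocks fitting. Zero-variance
columns are reported as degenerate and excluded from the correlations.

## The hierarchical negative-binomial model

See the README for the equations. Two parameterization choices deserve
record, because the model family originates in BUGS-dialect samplers whose
conventions differ from most Python libraries:

- **Normal priors are (mean, precision).** `normal(0, 0.1)` means variance
  10. Read as a variance, 0.1 would shrink every coefficient to near zero,
  which is inconsistent with coefficient magnitudes near one being
  estimable; read as precision it is the intended weakly-informative prior.
  Likewise τ_α is the precision of the random intercepts (variance 1/τ_α).
- **The dispersion link is p = r/(r+λ)**, chosen so that λ from the process
  model is exactly the distribution's mean and Var = λ(1 + λ/r). The PMF is
  evaluated through log-gamma functions so r may be any positive real.

### Sampler

Inference is adaptive Metropolis-within-Gibbs: componentwise Gaussian random
walks on each β_k and on μ_α; a simultaneous block of independent
componentwise moves on the α_j (valid because the likelihood factorizes over
focals given everything else); and random walks on logit-type transforms of
the bounded τ_α and r with the log-Jacobian included. Proposal scales adapt
toward 0.44 acceptance in batches of 50 during burn-in only — adaptation is
frozen afterwards, so the recorded chain is a valid Markov chain with the
posterior as its stationary law. Defaults mirror the analysis protocol:
3 chains, 100,000 iterations, first 10% discarded, no thinning, chains
pooled for summaries. Chains start from independent prior draws (bounded
parameters from their uniforms), giving overdispersed initial values for the
convergence diagnostic. Runs are deterministic given the seed; per-chain
streams are spawned from one seed sequence.

The hot log-likelihood kernels are numba-compiled and drop terms constant
across each move type; the exact normalized `log_posterior` is kept as a
separate, plainly-written function and is pinned to an independently coded
brute-force evaluation in the tests.

Convergence uses the classic Gelman–Rubin potential scale reduction,
R̂ = √[((n−1)/n·W + B/n)/W], per parameter across chains, with R̂ < 1.1 as
the bar. Identical degenerate chains give R̂ = 1; zero within-chain variance
with separated chains is reported as undefined. Summaries are posterior
medians with equal-tailed 95% credible intervals from the pooled draws.

Numerical guards: ln(r + e^v) is computed in overflow-safe form; a
non-finite expected count raises rather than propagating; acceptance rates
outside [0.05, 0.95] after adaptation trigger a warning.

## Synthetic data

The generator emulates the study's structure at its scale: 12 core groups of
4 focal females each (48 focals, 60% orphaned, matching the study's roughly
half-and-half strata), each group a three-generation unit — a matriarch
(grandmother), her adult daughters (the focals' mothers and aunts), the
focal females (ages 8–16 at the study midpoint), optional maternal sisters,
aunts' young calves and cousins — plus dispersed bulls shared across groups.
Orphans' mothers die mostly before, occasionally during, the three-year
observation window; the age at orphaning is drawn directly on 1–12 years so
that it stays decorrelated from focal age (a death-date-driven construction
would make the two collinear and trip the screen).

Follows are drawn per focal (Poisson counts around 18 feeding / 4 resting
follows, durations uniform on 8–30 minutes, distinct days), with per-follow
presence sampled independently per candidate: 0.65 for same-group members,
0.12 for bulls, 0.03 for other groups. These choices reproduce the study's
reported sampling-effort profile (hundreds of feeding minutes and a handful
of resting follows per focal; total hours of the same order as reported).
Baseline rates are exp(μ_α) ≈ 0.02/min feeding and ≈ 0.15/min resting,
random-intercept precision τ_α = 4 (sd 0.5), dispersion r = 1.5; default
coefficients echo the magnitudes of the fitted field models (|β| ≤ 1.3).

Counts are drawn at dyad level from the negative binomial at mean
γ·exp(α_j + β′x) and scattered multinomially (duration-weighted) over the
follows where the partner was present; the analysis consumes dyad totals, so
within-follow placement is free. A sprinkle of non-affiliative events
exercises the filter.

What the generator does **not** emulate: temporal autocorrelation of
aggregation membership (real fission–fusion visits are bursty, not
independent per follow), seasonal structure, observation error in identity
or event classification, and association-driven group definitions (core
group membership is an input here). Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness of the field inferences to violations of them.

## Recovery experiment and problem sizes

The recovery experiment simulates a 30-focal, all-orphan feeding study
(~40 candidate partners per focal, ~1,100–1,600 dyads), refits with 3 chains
× 10,000 iterations, and scores per-coefficient bias, RMSE, and 95%
credible-interval coverage over 50 replicates, excluding (and counting) any
replicate with R̂ ≥ 1.1. The shortened chains and desk-scale population are
the package's default verification sizes — large enough that every
coefficient, including the rarer categories (matriarch: one strong dyad per
focal), is informed by the data, while a full experiment completes in
minutes on one CPU. At these sizes the posterior is likelihood-dominated, so
bias within ±0.1 and coverage inside the binomial band [0.86, 1.0] around
nominal are the expected outcomes for a correct sampler.

## Known limitations

- The Kruskal–Wallis χ² approximation is anti-conservative for very small
  groups; the exact option exists but is not the default, to match the
  reporting convention being reproduced.
- The matriarch flag is evaluated at the study midpoint; a group whose
  matriarch died mid-study would be better served by per-date evaluation.
- Focal-level covariates (age, age orphaned) compete with the random
  intercepts; their identification rests on the hierarchical shrinkage of
  α_j, and weakens as τ_α decreases.
- The sampler is a random-walk scheme: effective sample sizes per iteration
  are modest, which the long default chains compensate.
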
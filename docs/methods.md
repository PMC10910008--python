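# Methods

This note records the modelling choices, defaults and numerical
conventions of `caninerx`, and what validation on synthetic data does and
does not establish.

## Study design being emulated

The unit of analysis is a dispensing *transaction*: one antibiotic sale to
one dog, with demographics (weight in kg, age in years, sex, neuter
status), a positive cost, and four binary keyword flags marking whether
the concurrent clinical notes referenced the gastrointestinal,
respiratory, urinary or skin organ systems. Dogs appear in multiple
transactions; drug choice is a 13-category outcome dominated by
co-amoxiclav.

## Cohort construction

Exclusion rules run in a fixed order and are tallied per rule: missing
weight; non-positive cost (free replacements and refunds); age above
`max_age` (default 25 y — a generalization of the observed corrupt
119–121 y band); weight above `max_weight` (default 100 kg, generalizing a
recorded 145 kg terrier); unknown sex (sex is a model covariate; a
descriptives-only flag retains these rows); finally any drug dispensed to
fewer than `min_patients_per_drug` (default 10) unique patients is dropped
entirely, because a handful of patients cannot support patient-level
random effects in that contrast. Exclusion is idempotent and the report
reconciles exactly with row counts. Breed is accepted but ignored
(free-text, unreliable); the keyword flags are taken as given — the
note-matching that produced them is upstream of this package.

## Multiple-membership weighting

A transaction referencing k ≥ 1 organ systems carries weight 1/k on each
referenced system and 0 elsewhere; with k = 0 the "unspecified" category
gets weight 1. Weights therefore always sum to one per transaction. Organ
effects enter the fixed-effect design through these weighted columns.

**Identifiability.** The five organ columns sum to the intercept column,
so the full 11-column design is exactly rank-deficient. `build_pair_dataset`
constructs it anyway (it is the natural reporting layout), but fitting and
orthogonalization require a full-rank design: pass
`drop_organ="unspecified"` (the default in the CLI and pipeline), which
absorbs the unspecified category into the intercept and makes each organ
coefficient the contrast against an unspecified-organ transaction. This is
this package's identification choice; software treating organ membership
as a random classification resolves the same redundancy through the
random-effect prior instead.

## Likelihood, priors, sampler

Each focal-vs-reference contrast is a binomial logistic model with linear
predictor x'β + u_j and u_j ~ N(0, σ_u²) per patient. Priors are diffuse:
β ~ N(0, 10⁶) iid and Gamma(0.001, 0.001) on the precision 1/σ_u²
(conventional diffuse choices for multilevel MCMC; the β prior applies in
whichever basis is sampled). Both a linear age term and √age are included;
the square-root term captures age-restricted prescribing (e.g. drugs
avoided in puppies or reserved for them) and, combined with the linear
term, yields possibly non-monotone partial effects.

The sampler is Metropolis-within-Gibbs:

- β updated as one block by random-walk Metropolis with a proposal shaped
  by the inverse Fisher information at a ridge-penalized logistic fit
  (also the chain's starting point), scalar scale adapted toward 0.23
  acceptance during burn-in only;
- all patient effects updated in one vectorized sweep of scalar random
  walks (they are conditionally independent given β and σ_u), per-patient
  scales adapted toward 0.44 during burn-in;
- the precision updated by its conjugate Gamma(a + J/2, b + Σu²/2) full
  conditional.

Adaptation freezes at the end of burn-in, so retained draws come from a
fixed Markov kernel. Non-finite deviance aborts with diagnostics. Chains
are deterministic given (seed, config).

**Parameterization.** Sampling can run in the raw basis or in a
QR-orthogonalized basis with column norms preserved (X' = Q·diag(‖x_j‖)),
whose exact back-transform β = R⁻¹diag(‖x_j‖)β′ is applied before
storage, so reported draws are always in the original basis. Raw
covariates (weight, age, √age) are strongly correlated, so the orthogonal
basis usually mixes better; `compare_parameterizations` fits both and
selects by DIC (DIC = D̄ + pD, pD = D̄ − D(θ̄) at the posterior mean of
(β, u)), breaking exact ties toward orthogonal.

**Protocols.** The full-scale protocol is burn-in 10,000, then 3,000,000
iterations retaining 1,000,000 ("retaining" read as thin-by-3; a
retain-last-third option is deliberately not the default). The default
desk-scale protocol — used throughout the tests, examples and the
acceptance script — is burn-in 1,000, 20,000 iterations, thin 2 (10,000
retained draws), which on the ~5,000-row simulated contrasts used for
validation yields a few hundred effective draws for the weight
coefficient, enough for the recovery checks below. Patient-effect draws
are summarized by a running mean (needed for DIC) rather than stored;
`store_u=True` keeps them for small problems.

## Diagnostics

- **ESS** = N / (1 + 2Σρ_t) with sample autocorrelations summed to the
  first nonpositive estimate (initial-positive-sequence truncation,
  chosen for robustness over fixed-lag windows). A constant chain reports
  ESS 0 with a warning. ESS is affine-invariant and never exceeds N.
- **Raftery–Lewis** (defaults q = 0.025, r = 0.005, s = 0.95, i.e. the
  endpoints of a 95% credible interval to ±0.005 with 95% probability):
  dichotomize at the empirical q-quantile, pick the smallest thinning k
  whose binary chain passes a first- vs second-order Markov BIC
  comparison, estimate the transition probabilities, and report burn-in
  M, recommended length N, Nmin = Φ⁻¹((1+s)/2)²q(1−q)/r² (3,746 at the
  defaults) and dependence factor I = N/Nmin.
- Trace and running-mean plots per parameter, deterministically
  downsampled, for visual inspection.

## Reporting

Odds ratios are exp(posterior mean coefficient) with exponentiated
equal-tailed 2.5/97.5-percentile intervals (posterior-median option
available). The p-value is reconstructed from the interval: SE =
(ln hi − ln lo)/(2·1.96), z = ln(OR)/SE, exactly p = 2(1 − Φ(|z|)) or by
the published approximation exp(−0.717|z| − 0.416z²). The approximation
is accurate to about the third decimal of p; its *relative* error grows
in the far tail (≈47% at z = 5), which is immaterial at reporting
precision ("< 0.001"). Display follows table convention: three decimals,
"< 0.001" below. Partial-effect curves are exp(β_w(w − 18)) over
(1, 70] kg and exp(β_a(a − 7) + β_√a(√a − √7)) over (0.25, 16] y, pinned
to 1 at the reference dog (18 kg, 7 y).

## Synthetic data generator

Defaults are the emulated study conditions: 14,259 dogs; weight
log-normal with mean 18.2 / sd 11.6 kg (log-normal for positivity, given
only two moments); age truncated-normal on (0, 25] with mean 7.1 / sd
4.5 y, the (loc, scale) solved numerically so the *truncated*
distribution has those moments exactly; 50.5% male, 1.5% unknown sex,
61.7% neutered; per-dog transaction counts zero-truncated geometric with
mean 1.8 (implying 56% single-prescription dogs and 96% with ≤4 — a
one-parameter family cannot also hit an observed 60% exactly); organ
flags independent Bernoulli at marginal prevalences (28.9%, 25.7%,
18.6%, 56.0%); dates uniform over Feb 2020–Feb 2022 and costs log-normal,
both purely plumbing. Drug labels come from a forward multinomial logit
whose non-intercept coefficients default to the log odds ratios of the
emulated study's fitted contrasts, with per-patient, per-contrast
N(0, σ_u²) effects (default σ_u = 0.5); intercepts are calibrated by
iterative proportional fitting so expected shares match the observed
prescription shares. The artifact injector appends rows violating each
data-quality rule, tagged in an `artifact_rule` column.

Not emulated: organ-flag co-occurrence (only marginals are matched, so
the generator's no-flag rate is ~19% rather than the observed 23%),
drug-specific patient concentration (a drug used 68 times in 9 animals),
seasonal or clinic structure, and any free-text notes. Recovery tests on
this generator therefore validate the *inference machinery* — that the
sampler finds coefficients that truly generated the data — not the
clinical conclusions of any real cohort.

## Validation summary

What the test suite establishes, at desk scale: exact conjugate algebra;
likelihood/posterior equal to brute-force density assembly at 1e-12;
maximum-likelihood recovery of a known weight effect from 50k generated
transactions (independent logistic-fit oracle); MCMC recovery across 20
replicates of ≈5,000-transaction two-drug studies with per-kg OR 1.13 and
σ_u = 0.5 (95%-interval coverage ≥ 16/20, |mean bias| < 0.02 on the
log-odds scale); ESS within 5% of the analytic AR(1) value and agreeing
with an independent implementation (different truncation rule, hence
median-level agreement); Raftery–Lewis Nmin equal to its closed form with
sane iid and strongly-autocorrelated behaviour; and the descriptive layer
reproducing every number that is recomputable from printed inputs alone
(shares 62%/14.2%, mean 1.8 prescriptions/dog, the 64.2% demographics
cell, the 0.001 interval-derived p-value).

## Known limitations

- One contrast at a time: no joint multinomial model (patient effects are
  re-estimated per pair, as in the emulated series-of-binomials design).
- Organ systems as weighted fixed effects, not a random classification
  (see Identifiability above).
- Gamma(0.001, 0.001) on the precision is kept for fidelity to the
  emulated protocol despite its known sensitivity when σ_u ≈ 0.
- Single-chain diagnostics only, by design.
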
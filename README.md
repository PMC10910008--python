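# caninerx

Does a dog's body weight change *which* antibiotic it is dispensed? Because
drug doses scale with weight, the cost of a course rises steeply for large
dogs, and cost pressure can push prescribers toward cheaper (sometimes less
suitable) drugs. `caninerx` is a toolkit for analysing this question in
first-opinion veterinary EHR data: it models the odds of dispensing each
antibiotic against the dominant choice, co-amoxiclav, as a function of
weight, age, sex, neuter status and the affected organ systems, while
accounting for repeated prescriptions within a patient.

Because clinic-level dispensing data are rarely shareable, the package also
ships a synthetic EHR generator that emulates the structure of such data —
including the data-quality problems (impossible ages, refund rows, missing
weights) that the cohort-building stage must handle — with ground-truth
parameters stored alongside, so the whole inference pipeline can be
validated by parameter recovery.

## The model

Transactions are nested in patients, and each transaction may reference
several major organ systems (gastrointestinal, respiratory, urinary, skin)
— a *multiple membership* structure. Each organ category referenced by a
transaction receives weight 1/k (k = number referenced; a transaction with
no reference belongs wholly to an "unspecified" category), so every
transaction's weights sum to one.

Drug choice is decomposed into a series of binomial contrasts. For focal
drug *d* versus the reference, transaction *i* of patient *j*:

```
logit P(y_i = 1) = x_i'β + u_j,      u_j ~ N(0, σ_u²)
x_i = (1, weight, age, √age, male, neutered, w_GI, w_resp, w_uri, w_skin, w_unspec)
```

with diffuse priors β ~ N(0, 10⁶) and 1/σ_u² ~ Gamma(0.001, 0.001).
Posteriors are sampled by adaptive Metropolis-within-Gibbs (conjugate Gamma
update for the precision), optionally in an orthogonalized fixed-effect
basis which typically mixes better; the two parameterizations are compared
by DIC. Convergence is assessed by effective sample size, the
Raftery–Lewis run-length diagnostic and trace inspection. Results are
reported as odds ratios with 95% equal-tailed credible intervals and
p-values derived from the interval by the Altman–Bland method, plus
partial-effect curves for weight (relative to an 18 kg dog) and age
(relative to a 7-year-old, combining the linear and √age terms).

## Worked example

```python
import caninerx as cx

# a synthetic two-year study: ~2,000 dogs, 13 drugs, injected bad records
table, truth = cx.generate_study(cx.PopulationConfig(n_patients=2000, seed=1))
cohort, report = cx.apply_exclusions(table)
print(report.excluded)
# {'missing_weight': 3, 'nonpositive_cost': 6, 'implausible_age': 3,
#  'implausible_weight': 5, 'sex_unknown': 56, 'rare_drug': 17}

print(cx.prescription_shares(cohort).head(3))
# drug
# co-amoxiclav     62.9
# metronidazole    15.0
# clindamycin       8.5

design = cx.build_pair_dataset(cohort, "metronidazole", drop_organ="unspecified")
est = cx.MultipleMembershipLogit(seed=1).fit(design)   # ~20k iterations
print(cx.or_table(est.chain_).loc["weight_kg", "display"])
# 1.01(1.00, 1.02) p = 0.103
```

The exclusion report shows each data-quality rule catching its injected
artifacts (plus two genuinely extreme simulated weights), the unknown-sex
animals, and the drugs dispensed to fewer than 10 unique patients at this
cohort size. The final line is the per-kg odds ratio of receiving
metronidazole rather than co-amoxiclav: the credible interval contains
this simulation's ground truth (OR 1.01 per kg).

The same stages are scriptable from a shell:

```bash
caninerx pipeline --n-patients 2000 --focal metronidazole --seed 1 --out study/
```

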
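# intero-update

Bayesian updating of prospective self-efficacy beliefs about cardiac
interoception: a tested, reusable pipeline for heartbeat-counting performance
scoring, precision-weighted belief-update modelling, BIC/MAE model comparison,
learning-rate analyses, and group-level / mediation statistics — exercised
end-to-end on synthetic cohorts emulating a three-group clinical study
(acute anorexia nervosa **AN**, post-acute **p-AN**, healthy controls **HC**).

## The scientific problem

People hold explicit, global beliefs about their ability to sense internal
bodily signals ("How well will I feel my heartbeat?").  After performing a
heartbeat-counting task (HCT), how do they revise those prospective
self-efficacy beliefs — and does that revision weigh the new evidence the way
an ideal observer would?  In anorexia nervosa such beliefs are typically
pessimistic and resistant to update despite normal task performance, and the
mechanism (a reduced learning rate, tied to mood comorbidity) is of direct
clinical interest.  This package is written for computational-psychiatry and
behavioural-modelling researchers who want that analysis chain as auditable,
reproducible code with a generator of synthetic study data to test it on.

## The model

Interoceptive accuracy on a counting trial with `rec` recorded and `cnt`
reported heartbeats is the Schandry score `1 − |rec − cnt| / rec`;
Performance is 100 × the mean over trials.  Belief updating is a one-shot
conjugate-Gaussian rule: with prior belief μ_θ, evidence y, and precision
weights π_θ (prior) and π_ε (evidence),

    μ_θ|y = μ_θ + λ (y − μ_θ),        λ = π_ε / (π_θ + π_ε),

where λ is the precision-weighted learning rate.  The realised learning rate
recovered from data is λ_actual = (μ_θ|y − μ_θ) / (y − μ_θ), and
|λ_actual − λ| is the Bayesian-optimality gap.  Competing prediction rules
instantiate the update with observable stand-ins — evidence is either
measured Performance or the posterior retrospective belief; evidence
precision is either performance confidence or the EDI-3 Interoceptive
Deficits score rescaled to a 0–100 success rate — plus λ=1 / λ=0 baselines.
Rules are compared by profiled-Gaussian BIC with MAE alongside; the
statistical layer provides HC-referenced group regressions, a per-trial
mixed model with participant and site random intercepts, a BIC-approximation
Bayes factor, Holm correction, and Baron–Kenny mediation of mood on learning
rates.

## Worked example

```python
import intero_update as iu

# one belief update: prior 40, evidence 60, precisions 20 (prior) / 60 (evidence)
lam = iu.precision_weighted_lambda(20, 60)
post = iu.posterior_belief(iu.BeliefUpdateInputs(40, 60, 20, 60))
print(f"lambda = {lam:.2f}, posterior = {post:.1f}")

# a synthetic cohort under the reference study conditions
cohort = iu.generate_cohort(iu.default_config(), seed=1)
derived = iu.derived_table(cohort.participants, cohort.trials)

# model comparison on the healthy-control panel
table = iu.compare_models(derived, iu.full_model_registry(), "HC")
for f in table.fits:
    print(f"{f.panel_label:>4s}  MAE={f.mae:6.2f}  BIC={f.bic:8.2f}"
          + ("  <- winner" if f.spec.label == table.winner else ""))

# group regression of the precision-weighted learning rate (HC reference)
rates = iu.cohort_learning_rates(derived, iu.spec_by_label("x.2")).reset_index()
res = iu.ols_group_regression(rates, "lambda_weighted", covariates=())
print(res.terms[["term", "beta", "se", "t", "p"]].round(4).to_string(index=False))
```

prints

```
lambda = 0.75, posterior = 55.0
 2.1  MAE=  4.48  BIC=  404.87
 2.2  MAE=  2.45  BIC=  266.68  <- winner
 2.3  MAE=  5.50  BIC=  470.57
 2.4  MAE=  3.87  BIC=  409.29
 b.1  MAE= 12.10  BIC=  649.97
 b.2  MAE= 11.83  BIC=  646.19
 b.0  MAE=  9.82  BIC=  600.24
     term    beta     se       t      p
Intercept  0.4592 0.0145 31.7478 0.0000
       AN -0.0677 0.0301 -2.2469 0.0258
     p-AN  0.0050 0.0287  0.1753 0.8610
```

The first line is the update rule itself: with three times more precision on
the evidence than the prior, λ = 0.75 and the belief moves three quarters of
the way from 40 to 60.  In the comparison block, rule 2.2 (retrospective
beliefs as evidence, performance confidence as its precision) wins on the HC
panel — it is the rule this cohort was generated under — and both fixed-λ
baselines fit far worse.  The regression recovers the generative learning-rate
structure: an HC mean near 0.47 and a significantly lower AN rate.

A command-line interface wraps the same pipeline:

```sh
intero-update generate --seed 2 --out cohort/
intero-update analyze --data cohort/ --out analysis/
intero-update simulate-study --replicates 10 --seed 1 --out sims.json
```

`analyze` writes the derived-measures table, per-model predictions, the
four-panel comparison grid, learning-rate and optimality tables, the
regression/Bayes-factor/mediation report, and a run log with the seed,
config hash, and exclusion ledger.

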
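# capri — conjoint analysis for prioritizing healthcare innovations

Healthcare organizations routinely face more candidate innovations than they
can implement. Which one gets adopted depends not only on cost-effectiveness
but on the values of the professionals who would have to change their
practice. `capri` implements a rating-based **Conjoint Analysis (CA)**
workflow for capturing those values and turning them into a defensible
priority order over competing innovations.

The method assumes an additive part-worth utility model: an innovation
described by attributes $a = 1..k$, each at one level $\ell_a$, has total
utility

$$U = \beta_0 + \sum_{a=1}^{k} \beta_{a,\ell_a},$$

where the part-worths $\beta_{a,\ell}$ are zero-centered within each
attribute. Stakeholders rate hypothetical innovations on a 7-point Likert
scale ("Very likely to prioritize this guideline" … "Very unlikely …"); the
ratings are regressed on the effects-coded attribute levels by ordinary least
squares to estimate the part-worths; real innovations, scored on the same
attribute grid, are then ranked by total utility.

The package covers the whole pipeline:

- **`capri.attributes`** — attribute/level spaces, with a packaged
  seven-attribute fixture for postnatal-depression (PND) innovations
  (impact on care, costs, local health needs, minimum standards, strength of
  evidence, priority status, local expertise).
- **`capri.design`** — deterministic orthogonal main-effects plans
  (Hadamard-derived arrays, 4-level pseudo-factors from XOR-closed column
  triples, Addelman collapsing to 3/2 levels), automatic run-count selection,
  dominance "consistency" holdout scenarios, and design diagnostics
  (frequencies, rank, D-efficiency).
- **`capri.simulate`** — synthetic respondents with individual part-worth
  heterogeneity and Likert discretization, defaulting to the published PND
  stakeholder utilities as the generating population.
- **`capri.estimate`** — pooled and per-respondent OLS part-worth estimation
  with effects coding, range-based attribute importance, holdout validation
  (Pearson r, r²) and dominance consistency checks.
- **`capri.prioritize`** — total utility, ranking, what-if sensitivity
  analysis and bundling of related innovations (with an 11-innovation PND
  fixture).
- **`capri` CLI** — `design`, `simulate`, `render`, `fit`, `validate`,
  `rank`, `whatif`, `run`.

## Worked example

```python
import capri

attrs = capri.builtin_pnd_attributes()           # 7 attributes, 864 profiles
plan = capri.generate_plan(attrs, "auto", seed=0)  # 16 scenarios
plan = capri.add_validation_scenarios(plan, 5, seed=0)  # + 5 holdouts

spec = capri.population_from_table6(n_respondents=139, noise_sd=0.5)
ratings = capri.simulate_ratings(spec, plan)      # 139 x 21 Likert ratings

model = capri.fit_pooled(ratings, plan)
report = capri.holdout_validation(model, ratings, plan)
ranking = capri.rank_innovations(model, capri.builtin_pnd_innovations())

print(f"holdout r^2 = {report.r_squared:.3f}")
print(ranking.records.head(3).to_string(index=False))
```

Output (seed 0):

```
holdout r^2 = 0.983
 rank                                                  name  total_utility
    1                                      Computerised CBT       4.557554
    2                                      Guided self help       4.487410
    3 Anti-depressants and psychological therapies together       4.129496
```

The holdout r² says the fitted model's predictions explain ~98% of the
variation in the observed mean ratings of the five held-out scenarios. Total
utilities include the rating-scale midpoint (the constant absorbs scale
location when fitting raw 1–7 ratings); only differences and order matter for
prioritization. The same run from the shell:

```sh
capri run --out artifacts/
```

writes the design, simulated responses, fitted model, importance table,
holdout report, consistency checks, ranking and a reproducibility manifest.

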
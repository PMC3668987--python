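# Methods

## The model

`capri` implements rating-based conjoint analysis. An innovation is a
profile on a fixed set of categorical attributes; its latent value to a
stakeholder is additive in per-level part-worth utilities:

    U(profile) = β0 + Σ_a β[a, level_a(profile)]

with the part-worths of each attribute constrained to sum to zero. The
assumptions inherited from this model class are the usual ones: preferences
are decomposable by attribute (no interactions), ratings are usable as
interval data, and the attribute list is complete enough that omitted drivers
of preference land in the error term.

## Design generation

A rating study cannot present the full factorial (864 profiles for the
packaged seven-attribute space), so scenarios come from an orthogonal
main-effects plan.

**Run count.** The main-effects model has `1 + Σ_a (L_a − 1)` parameters
(13 for the packaged space). `minimum_hadamard_runs` picks the smallest
power-of-two run size in {4, 8, 16, …} with at least that many runs — 16 for
the packaged space.

**Construction.** For `n = 2^k` runs, the saturated two-level array has
`n − 1` mutually orthogonal columns indexed by the nonzero vectors of
GF(2)^k (column *v* at run *i* is the parity of `i AND v`). XOR-closed
column triples `{a, b, a⊕b}` — lines of PG(k−1, 2) — are packed greedily
into disjoint sets; each line's two leading columns form a balanced 4-level
pseudo-factor, and disjoint lines give mutually orthogonal pseudo-factors
(for n = 16 the greedy packing recovers a full spread: five lines).
Attributes with 4 levels take a pseudo-factor as-is; 3-level attributes take
one collapsed by the fixed surjection 4→1 (frequencies n/2 : n/4 : n/4);
2-level attributes take single leftover columns. Collapsed columns satisfy
the Addelman proportional-frequency condition
`count(i,j) = count(i)·count(j)/n` against every other attribute exactly
(verified in tests), which keeps all main effects estimable.

The construction is deterministic; the seed only permutes run order and
which attribute gets which pseudo-factor/column. A safety loop re-draws the
assignment if collapsing were ever to produce duplicate runs or a
rank-deficient coding matrix (it does not for the packaged space, where the
uncollapsed 4-level factor plus the three 2-level columns already separate
all 16 runs).

**Limits.** Run sizes are powers of two, and at `n = 16` at most five
attributes may exceed two levels (the spread size) with none above four
levels. Spaces outside these limits raise a validation error rather than
falling back to a non-orthogonal design. There is no D-optimal search
(Fedorov/coordinate exchange) and no choice-set construction; those are
different design classes, out of scope.

**Diagnostics.** D-efficiency is `det(X'X/n)^(1/p)` of the effects-coded
estimation runs, normalized by the same quantity for the balanced full
factorial, whose moment matrix is block-diagonal with per-attribute blocks
`(I + J)/L` (determinant `L^(2−L)`) — so balanced orthogonal plans score
exactly 1, and the packaged 16-run plan scores ≈ 0.96 (the collapsed
columns' imbalance is the only loss).

**Consistency holdouts.** `add_validation_scenarios` appends scenarios
(default 5) that copy an estimation run with one or more attributes moved to
an a-priori preferable level. The rational orderings shipped for the
packaged space are: cost high<moderate<low; impact limited<moderate<
significant; evidence none<limited<moderate<strong; prevalence low<high.
Minimum standards, priority status and local expertise have no defensible
a-priori ordering and are never modified. By construction a holdout weakly
dominates its parent under any preference model that respects those
orderings, so it should score at least as high; the pairs double as holdout
tasks for predictive validation and are excluded from estimation. Note that
the published utility table is itself non-monotone in impact (see
"Fixture caveats"), so dominance checks against that table are only
guaranteed to pass when the orderings are restricted to cost, evidence and
prevalence.

## Synthetic respondents

No respondent-level data ship with the package, so the simulator emulates
the survey: each of `n_respondents` (default 139, the realized sample size
of the original postal/electronic survey) draws individual part-worths as
population means plus Normal(0, `heterogeneity_sd`) noise, re-centered to
stay zero-sum per attribute; each scenario's rating is

    clamp(round(midpoint + β0 + Σ part-worths + Normal(0, noise_sd)), 1, 7)

with rounding half away from zero and midpoint 4. Defaults:
`heterogeneity_sd = 0.1`, `noise_sd = 0.5`. The published part-worths have
magnitude ≤ 0.4 and profile totals within roughly ±1.6 of the constant, so
clamping is rare at these settings; `noise_sd = 0.5` yields holdout r² in
the 0.9+ range at N = 139, comparable to the strong validation reported for
the original survey. The default population is the published utility table
(`population_from_table6`); `continuous_output=True` skips discretization
(used by the exact-recovery tests), and `nonresponse_filter` drops
respondents all-or-none with a Bernoulli response rate (the original survey
achieved 11%).

What the simulator does **not** emulate: delivery-mode effects (postal vs
electronic), item nonresponse within a questionnaire, response styles
(straight-lining, extreme responding), attribute-order or learning effects,
and any non-additive preference structure. Passing tests therefore show the
estimator recovers the generating additive model from discretized, noisy,
heterogeneous ratings — not that real stakeholder behaviour is additive.

## Estimation

`fit_pooled` stacks every respondent's ratings of the estimation runs and
solves one OLS regression on the effects-coded matrix. Part-worths for
reference (last) levels are decoded as minus the sum of the attribute's
contrasts, with standard errors from the corresponding linear combination of
the coefficient covariance. Standard errors default to the homoskedastic
OLS formula, which ignores the within-respondent correlation that
heterogeneity induces; `cluster_robust=True` provides respondent-clustered
errors (point estimates unchanged). `fit_individual` fits each respondent
separately (requiring complete coverage of the estimation runs; incomplete
respondents are excluded with a logged warning) and returns the
arithmetic-mean model, whose point estimates coincide with the pooled fit on
complete balanced data — an algebraic identity the tests verify numerically.

Ratings enter as raw 1–7 values: the constant absorbs the scale midpoint,
and predictions/total utilities are therefore on the rating scale. On
continuous simulated data generated with midpoint 0 the fitted constant
equals the generating constant. (The small constant in the published table
suggests the original analysis centered ratings before regression; both
conventions are reachable here — fit raw and subtract the midpoint, or
simulate with midpoint 0.)

**Importance.** Range-based, the standard conjoint convention: an
attribute's importance is `(max − min part-worth) / Σ ranges`, ranked
descending with ties broken by attribute order. The original report does not
state its importance formula; range-based is what classic conjoint value
analysis software computes.

**Validation.** `holdout_validation` correlates model predictions with
observed mean ratings across the consistency scenarios (≥ 2 required,
Pearson r and r²); `consistency_check` flags, per dominance pair, whether
the dominating scenario scored at least its parent (observed means or model
predictions).

## Prioritization

Real innovations are scored on the attribute grid as input data — the
scoring step is evidence-based but subjective, which is exactly why
`what_if` exists: it recomputes one innovation's total and rank after a
single level change, quantifying how sensitive the priority order is to a
scoring judgement. Ranking is by descending total utility with alphabetical
tie-breaks (recorded in the output provenance). `combine_innovations`
bundles related innovations; the bundle's utility is reported as the max and
the mean of member totals, never a sum — summing would double-count the
constant and has no interpretation under the model.

## Fixture caveats

- The packaged candidate list has 11 innovations. The original project
  described 12, but only 11 appear in the published assessment grid; the
  twelfth (apparently a second screening/diagnostic variant) is
  unrecoverable and is not invented here.
- The published utility table gives impact on care a *negative* part-worth
  for "significant improvement" (−0.228) and a positive one for "limited"
  (+0.150), contradicting the accompanying narrative that significant impact
  was preferred. The fixture reproduces the table as printed;
  `population_from_table6(impact_reversed=True)` provides the alternative
  reading with the impact column flipped. No result that depends on
  resolving this ambiguity is asserted anywhere.
- The published "Innovation B" total (−0.15) cannot be reproduced from any
  single level assignment consistent with its description, so it is not used
  as a reference value; the "Innovation A" total (0.94) can, and is.

## Numerical choices and problem sizes

- Zero-sum and recovery tolerances: part-worth zero-sums are enforced at
  1e-9; exact-recovery tests assert ≤ 1e-8; pooled-vs-averaged-individual
  agreement at ≤ 1e-10.
- Degenerate inputs: constant ratings yield zero part-worths and an R²
  defined as 1 (nothing left to explain); zero-variance holdout vectors are
  an error rather than a NaN correlation.
- Sampling-error experiments use 20 replicates at n ∈ {10, 50, 200}
  respondents with noise SD 0.5 — enough replication for the mean RMSE to
  decrease monotonically in n, while keeping the full test suite in the
  seconds range.
- All randomness flows through `numpy.random.default_rng` seeds carried on
  the objects (population spec, plan); identical seeds reproduce identical
  artifacts byte for byte, which the pipeline manifest test asserts.
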
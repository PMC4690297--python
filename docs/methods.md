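# Methods

## Model structure and assumptions

The model is a probability tree rolled back by expectation. One store visit by one
adolescent proceeds:

1. **Preference group.** The shopper belongs to one of four groups with equal
   weight 1/4 — the groups are quartiles of the proportion of non-SSB beverages
   among purchases, so equal weights are structural, not an estimate. Each group
   carries a range of non-SSB purchase probability (in percent): always-SSB `[0, 0]`,
   usually `[0, 28.4]`, sometimes `[28.5, 54.4]`, rarely/never `(54.4, 100]`. The
   open top range is closed at 100 because a proportion of purchases cannot exceed
   100%.
2. **Shopper type.** With probability `conv_g = conv_baseline x loyalty_g` the
   shopper is a *convenience shopper* who only stands at the cooler nearest the
   entrance; otherwise a *browser* who considers all coolers. `conv_baseline = 0.326`;
   loyalty weights are 0.27 / 0.75 / 1.00 / 0.27 by group (brand-loyal SSB drinkers
   and committed non-SSB drinkers are assumed likelier to browse for their usual
   choice). The product is clipped to 1, which only matters for user overrides.
3. **Slot selection.** All shoppers weight shelves by the vertical shares
   `v = (17.0, 17.2, 17.1, 16.8, 16.3, 15.5)` (top to bottom, peaking at eye level);
   browsers additionally weight coolers by the horizontal shares
   `h = (17.9, 17.4, 16.9, 16.4, 15.9, 15.4)` (front to back), multiplicatively.
   Convenience shoppers select within cooler 1 only.
4. **Purchase gate.** Conditional on selecting the focal product's slot, the
   purchase succeeds with the group's base probability. At most one beverage is
   bought per visit; price, package size and facings are held equal by assumption
   and are out of scope.

The shares are used exactly as published, where each axis sums to 99.9 rather than
100. The 0.1% shortfall is a no-purchase path; it cancels identically from every
relative ratio, so no renormalization is applied (renormalizing would perturb
ratios by < 0.2%, well inside Monte-Carlo noise at the published cohort size).

Because the purchase gate is multiplicative, the base preference cancels from each
stratum's relative grid; strata differ in their ratios only through loyalty. The
always-SSB stratum has zero probability everywhere, so its relative grid is
reported as all-1.0 with a `no_effect` flag rather than a 0/0 error.

## Point preferences: midpoint vs uniform draw

How a point probability is taken from a group's quartile range is genuinely open;
the package supports both a deterministic **midpoint** rule (the default) and a
per-individual **uniform draw** within the range. The base preference enters the
tree linearly, so the midpoint equals the expectation of the uniform draw and the
analytic results coincide; the draw mode only widens Monte-Carlo dispersion. A test
confirms the equivalence empirically across seeds.

## Grids, reference cell, and the optimum

Relative grids divide every cell by the worst slot, cooler 6 / shelf 6; the
reference cell is set to exactly 1.0 (not merely within floating error). A zero
reference probability (e.g. all base ranges collapsed to zero) raises a dedicated
error, signalling degenerate parameters rather than returning infinities.

The optimum search reports every cell within a relative *tie tolerance* of the
maximum, default 1%: the front cooler's shelves 2 and 3 differ analytically by only
~0.6% (shelf shares 17.2 vs 17.1), and reporting them jointly optimal reflects that
the separation is far below any practical or sampling resolution. Tolerance 0 gives
the strict argmax, shelf 2.

## Monte-Carlo simulation

A synthetic cohort (default n = 1000, the published simulation size) is generated
with balanced group assignment (round-robin, so group sizes differ by at most one),
a per-individual base preference, and a Bernoulli convenience/browser label at
`conv_g`. A purchase is one Bernoulli trial per individual at probability
`base x slot share`. Randomness uses numpy `SeedSequence` sub-streams derived from
one root seed per purpose (cohort, purchase draws, and per-replicate/per-location
streams in ratio summaries), so each stage is independently reproducible.

Simulated optimal-vs-worst ratios are ratios of purchase counts from two
*independent* cohorts. At n = 1000 the worst cell expects only ~6.5 purchases, so
the count ratio is wide and upward-biased (E[1/X] > 1/E[X]); the summary therefore
reports mean, SD and the central 95% interval over replicates rather than a single
number. A replicate with a zero denominator count is discarded and redrawn with the
discard tallied — the published analysis reports ratios without addressing the zero
case, and conditioning on a defined ratio is the least-intrusive resolution. If a
configurable redraw budget is exhausted the summary raises instead of silently
degenerating.

Test sizes: convergence checks use n = 100,000 (3-standard-error binomial bands)
and n = 10^6 for law-of-large-numbers checks on ratios, chosen so the bands are a
few percent wide; distribution-coverage checks use the published n = 1000 with 300
replicates. All stochastic tests run under fixed seeds and complete in seconds.

## Sensitivity scenarios

Five one-way scenarios: always-SSB base preference raised to a 25% point mass;
convenience baseline doubled (0.652) and halved (0.163); horizontal and vertical
effects doubled and halved simultaneously. "Doubling/halving an effect" is a
mean-preserving spread of the share list,
`scaled_i = mean + factor x (share_i − mean)` with `mean = Σ shares / 6`, followed
by half-up rounding to one decimal. This rule regenerates 23 of the 24 published
scaled shares exactly; the single exception (halved vertical, top shelf: published
17.1, rule 16.8) is treated as a typo, as is the published half-convenience value
18.3 (half of 32.6 is 16.3). The scaling arithmetic runs in `decimal` so the
half-up boundary (e.g. 17.35 → 17.4) is immune to binary-float artifacts. A scaled
share that reaches zero or below raises an error.

Scenario ratios are always evaluated at the fixed cells (cooler 1, shelf 2) vs
(cooler 6, shelf 6): the optimal location does not move across the published
scenarios, and fixing the cells keeps the column comparable even where extreme
user-supplied factors would shift the argmax.

The analytic reconstruction of the always-SSB-25% scenario yields ≈ 2.71 where the
published table prints 3.50; the other four scenarios and the baseline agree with
the published simulated values within their n = 1000 sampling noise. The
discrepancy is reported as computed, not matched; a different loyalty assumption
for that scenario, or a high single simulation draw, would both explain it, and
neither can be confirmed from the published material.

## Projection

Annual additional purchases = `population x visits_per_year x [P(to) − P(from)]`,
rounded to the nearest integer at the end (the three canonical moves —
worst→optimal, worst→second-best, second-best→optimal — are exactly additive
before rounding). Population and per-capita visit rate are required inputs with no
defaults: they are census- and survey-specific and not part of the model. With
illustrative inputs of 10^6 adolescents at 430 visits/year, the worst→optimal move
projects ~5.2 million additional non-SSB purchases per year, which indicates the
magnitude such inputs produce; it is a demonstration, not a reproduction of any
surveyed population.

## What the synthetic cohort does and does not emulate

The generator reproduces the *modelled* population: quartile structure, loyalty-
modified shopper types, and independent single-visit Bernoulli purchases. It does
not emulate repeat visits, habit formation, price or promotion response, correlated
preferences within neighborhoods, or seasonality — so passing tests validate the
decision-tree machinery and its published parameterization, not the behavioral
realism of those parameters for any particular real population.

## Numerical notes

* Closed-form cell probabilities agree with a brute-force enumeration of every tree
  path to ≤ 1e-12 (tested on all 36 cells and under randomized parameters).
* Grid CSV exports use 4 decimal places, rows `cooler_1..6`, columns `shelf_1..6`.
* Config round-trips through YAML bit-stably; any invariant violation on load is an
  error, never a warning.
* All validation errors derive from `ValueError` (`ParameterError`, `ConfigError`),
  so callers can catch broadly or precisely.

## Known limitations

* Loyalty and placement-share parameters originate from non-beverage retail
  studies; the sensitivity suite brackets but cannot remove that transfer
  assumption.
* The model is single-visit and static; displacement effects on SSB purchases are
  not modelled (the projection counts additional non-SSB purchases only).
* The published 3.50 ratio for the always-SSB-25% scenario is not reproduced by the
  analytic reconstruction (see above).
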
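# Methods

## Decision model

The package models the diagnostic episode of a population eligible for
an invasive confirmatory procedure as a two-arm decision tree. In the
comparator arm every patient undergoes the procedure. In the
intervention arm every patient takes a rule-out test; only positives
proceed to the procedure. The time horizon ends at the procedure, so
costs are not discounted, and downstream treatment costs and utilities
are out of scope: outcomes are presented as *consequences* (fractions
of the population with missed, i.e. delayed, diagnoses) next to costs
rather than folded into a cost-per-QALY ratio.

Assumptions:

* Test and procedure results are conditionally independent of
  everything but disease status and score band; there is no repeat
  testing or monitoring cost for test-negative men within the horizon.
* The test is administered to the entire eligible population at full
  unit cost (no volume discount).
* The adverse-event cascade is procedure → A&E attendance →
  hospitalisation; a hospitalised patient pays both the attendance
  cost and the stay cost.
* An optional refusal rate removes that fraction of would-be biopsies
  from both arms (refusers' cancers count as missed); the base case is
  zero. With refusal rate `r` the saving falls linearly and, for the
  built-in inputs, crosses zero near r ≈ 65%.

## Performance from banded counts

Score distributions are supplied as contiguous half-open bands
`[lower, upper)` with per-band counts of men, any-grade cancers and
high-grade (Gleason ≥ 7) cancers. A cut-off placed on a band boundary
splits the cohort exactly, so prevalence, sensitivity and specificity
are exact integer ratios; the implementation keeps them as
`fractions.Fraction` and only floats them at the economic layer. A
cut-off inside a band is refused (`UnresolvableCutError`) rather than
interpolated: no ROC smoothing is attempted. The half-open convention
puts a band whose upper bound equals the cut-off into the
test-negative arm.

The biopsy decision uses any-grade operating characteristics in the
base case; high-grade characteristics are carried alongside purely to
report the missed-high-grade consequence. The two grades are exposed
separately and never combined into a weighted score.

## Key parameters (built-in Hong Kong instance)

| parameter | value | units | note |
|---|---|---|---|
| cohort bands (<25, 25–35, 35–55, >55) | 192/7/1, 225/17/2, 131/30/9, 21/8/4 | men / any / high | 569 men total |
| P(A&E \| biopsy) | 39/569 | — | kept as the exact ratio, not 0.07 |
| P(hosp \| A&E) | 15/39 | — | kept as the exact ratio, not 0.38 |
| test cost | 3,000 | HK$ | private-clinic price |
| biopsy cost | 10,900 | HK$ | micro-costing |
| A&E attendance | 1,300 | HK$ | |
| hospital stay | 4.67 days × 4,950/day | HK$ | 23,116.5 per stay |

The rounded probability values printed alongside the counts in the
source tabulations do **not** reproduce the expected adverse-event
cost of ≈698.5 per biopsy; the exact count ratios do, which is why the
package stores ratios.

## Sensitivity, tornado and threshold analysis

One-way sweeps vary one scalar at a time, default ±50% of base with
probabilities capped at 1; explicit bounds override the defaults. The
built-in sweep list sets sensitivity's upper endpoint to 100% outright
(sweeping to certainty rather than to 1.5×base), matching how the
original analysis was run. The hospitalisation cost is swept as the
full stay cost; the daily rate and length of stay exist only to
construct the base case. Tornado entries are ordered by descending
swing of the saving, ties broken alphabetically for determinism.

The net saving is affine in every sweepable scalar (the biopsy rate is
affine in π, Se, Sp; costs enter linearly), so the cost-neutrality
threshold is solved in closed form from two model evaluations and then
verified with Brent bisection; the two must agree to 1e-6 relative and
the saving at the root must vanish to 1e-6 currency units. Search
domains are [0, 1] for probabilities and [0, 10×base] for costs; when
the saving does not change sign over the domain the solver reports
"no threshold in range" (this is the case for sensitivity, prevalence
and the A&E attendance cost at the built-in inputs). No probabilistic
(Monte-Carlo-over-priors) sensitivity analysis is performed.

One published sweep cell is knowingly not reproduced: the
lower-bound saving for P(hosp | A&E) as printed equals what the model
yields for the hospitalisation-*cost* lower bound (≈5,277), and no
parameterisation of this model produces the printed 4,831. The
package reports its own computed value.

## Microsimulation

The synthetic-cohort generator draws each patient's band from the
cohort's band weights, a score uniform within the band (the open top
band is capped at 100; scores affect only band membership), cancer
status from the band's grade mix, and — when biopsied — the Bernoulli
adverse-event cascade with length of stay `1 + Poisson(mean − 1)`
(only the mean matters for expected cost; the distribution guarantees
a hospitalised stay of at least one day). Each patient uses an
independent random sub-stream keyed by (seed, patient index), so
cohorts are byte-identical across runs and invariant to iteration
order.

The simulator emulates the statistical structure the closed form
assumes — band frequencies, within-band grade mix, the nested event
cascade — and nothing else: no PSA values, age structure, clinician
behaviour, correlated test errors or longitudinal re-screening. Tests
that pass against it therefore validate the internal consistency of
the engine (empirical means converge to the closed-form expectations
within 3 Monte-Carlo standard errors at n = 50,000, the suite's
standard problem size), not the external validity of the inputs.

## Numerical choices

* Count arithmetic is exact (integers/Fractions); money is computed in
  double precision and rounded half-up to whole units only for
  display, with thousands separators.
* Report CSVs are written with fixed formatting and a stable row
  order, so re-running a config reproduces the bundle byte for byte.
* Degenerate inputs: a cohort with zero cancers has sensitivity
  defined as 1 (nothing to miss); zero non-cancers give specificity 1;
  a cut-off at or below the bottom of the score range sends everyone
  to biopsy (Se = 1, Sp = 0); an empty cohort is rejected.

## Limitations

* Point estimates only: no confidence intervals on Se/Sp and no
  parameter distributions.
* The horizon excludes monitoring of test-negative men and the
  long-term cost and health consequences of delayed diagnoses, so the
  "saving" is a diagnostic-episode budget quantity, not a
  cost-effectiveness verdict.
* Threshold solving presumes the saving is monotone in the parameter
  over the search domain, which holds for every scalar in this model
  but is verified, not assumed, via the sign-change check.
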
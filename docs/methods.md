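# Methods

This note documents the model implemented in `cvdpolicy`: its structure and
timing conventions, the parameters that matter, what the synthetic-data
generators emulate, the numerical choices, and known limitations.

## State-transition structure

Individuals enter free of CVD and cycle annually for up to `horizon`
cycles (default 100, the maximum).  The states are: event-free; two
post-event states (after a first non-fatal CHD or CBVD event); and death.
Four competing first events are modelled — non-fatal CHD, non-fatal CBVD,
fatal CVD and fatal non-CVD death — with cause-specific conditional
probabilities applied simultaneously within a cycle (no within-cycle
ordering; the cycle is a year, and the data that would identify an
ordering do not exist at that resolution).  If the cause-specific
probabilities at any cycle sum above one the engine raises an error rather
than silently renormalising: such input is malformed and renormalising
would hide it.

Every event equation — first events, post-event death, subsequent
non-fatal events — shares one functional family: a probit link on a linear
predictor in named ASSIGN-factor terms plus a restricted cubic spline in a
time argument (cycle index for first events; years since the first event
for post-event and subsequent-event equations, with attained age always
advancing one year per cycle).  A single uniform family keeps the
parameter file format and the PSA machinery simple; separate parameter
sets per sex carry the sex difference, mirroring how such models are fitted
separately for men and women.

### Timing conventions

* Point `k` is the start of cycle `k`; attained age at point `k` is entry
  age + `k` (integer ages; the background-utility age band switches at the
  cycle where integer age enters the new band).
* An event at cycle `t` happens mid-cycle.  A fatal first event at `t`
  therefore credits `t + 0.5` life years — realised through the trapezoid
  rule on cycle-point values, which is the half-cycle correction in
  equivalent form.
* A non-fatal first event at `t` defines the state from point `t` onwards:
  the post-event conditional survival has S*(0) = 1 at point `t`, and the
  quality weight at point `t` already carries the first-event decrement
  and the composite decrement at years-since-event 0.
* Residual event-free survival at the horizon is booked as fatal non-CVD
  death at the final cycle, making the 4 × horizon scenario probabilities
  sum to one exactly (the forced-termination convention).
* Discounting is at interval midpoints, `(1 + r)^-(t + 0.5)` for cycle
  `t`, consistent with trapezoid areas.  Costs accrue through the year and
  are weighted by mid-cycle survival occupancy
  `(S(t) + S(t+1))/2`; this also gives the fatal-event-at-cycle-0 scenario
  exactly half a year of pre-event cost.  An optional terminal cost
  attached to the death cycle is supported and defaults to zero.

### Quality adjustment

The per-cycle quality weight is

    w = max(0, u(sex, age band, SIMD fifth) − δ_first − Σ_e p_e(u)·δ_e)

with background utilities on the SF-6D scale (each table cell must lie in
[0.29, 1]), the first-event decrement (MI for CHD, stroke for CBVD), and
the composite decrement over the five subsequent event types (CHD, stroke,
irregular heartbeat, intermittent claudication, heart failure), whose
annual probabilities are treated as independent.  Recurrent events of the
first event's own type contribute: the five-event list includes CHD in
both post-event states.  Decrements are additive on the utility scale with
a floor at zero; "worse than dead" states are out of scope.  The composite
decrement applies per cycle in expectation — an event risk this year
decrements this year's weight — rather than accumulating once incurred;
the floor is applied to the expected decrement.

## KMSA estimator and scenario expectation

The type and timing of the first event define a scenario (4 × horizon of
them).  Per scenario the engine builds the survival, quality-weighted
survival and annual cost series, integrates (trapezoid with half-cycle
correction; occupancy weighting for costs), discounts, and takes the
probability-weighted sum over the grid.  The implementation vectorises the
(event-cycle × years-since-event) grids so a full 400-scenario run takes
~15 ms; PSA and risk tables loop over such runs.

## Parameters

| Parameter | Units / range | Default | Why |
|---|---|---|---|
| `horizon` | cycles, 1–100 | 100 | an event must occur within 100 annual cycles |
| discount rates | /year, [0, 1) | 0.035 (health technology), 0.015 (public health) | appraisal-guidance defaults per evaluation mode, applied to LE, QALE and costs alike |
| utility bounds | SF-6D scale | [0.29, 1.0] | the preference-weighted index range |
| decrement bounds | utility scale | [0, 0.71] | cannot exceed the utility range width |
| age bands | years | 20–25, 25–34, …, 75+ | the seven standard bands; half-open, ties upward |
| SIMD cutpoints | score units | (8, 14, 21, 34) | population quintile boundaries are an input; defaults chosen so a score of 60.8 lands in fifth 5 (most deprived) |
| intervention lag / decay / adherence | years, /year, [0,1] | 0 / 0 / 1 | immediate, permanent, fully adhered by default |

Adherence multiplies the expected risk-factor change (cohort-level
deterministic reading); a Bernoulli-mixture mode that mixes a full-adherer
run with the baseline is available via `adherence_mode="mixture"`.
Reversibility is an exponential retention decay per year after the onset
lag.  Out-of-range post-intervention values are clamped to physiologic
bounds with a warning record.

Half-open binning with ties to the upper bin is used everywhere (SIMD
fifths, age bands).

## Uncertainty analysis

The flat parameter ordering covers every equation coefficient, the five
decrements, the cost-curve coefficients and the 70 utility-table cells;
the variance–covariance matrix is declared over that ordering.  PSA draws
are multivariate normal on the estimation scale (coefficients, not
probabilities — no transformation bias), correlated through the Cholesky
factor; positive semi-definite matrices are handled by clipping
eigenvalues (below 1e-12 to zero) with a warning, keeping null directions
exactly null.  Draws violating structural constraints (utilities or
decrements out of range, cause probabilities summing above one) are
rejected and the rejection rate reported — clamping would distort the
distribution — with an error if more than half the draws are rejected.
Analysis of extremes sets parameters jointly at mean ± z·SE, signed per
parameter by numeric perturbation of the QALE gain; one-way sensitivity
analysis reports the ICER at each parameter's CI limits, sorted by range.
Discount rates are varied by scenario analysis, not PSA.

## Synthetic data and oracles

`make_synthetic_params` generates a complete parameter set with known
truth.  Event-risk curves rise with age towards a plateau (probit scale),
with plateau levels chosen so the cause-specific probabilities cannot sum
above one for any plausible profile, and intercepts calibrated (by common
shift, when needed) so a reference individual's cumulative first-event
incidence by cycle 40 lies in [0.5, 0.99].  Plain mode keeps coefficient
signs monotone (raising a hazardous factor raises the matching event's
incidence); adversarial mode pushes utility cells to the 0.30 floor and
makes one vcov block near-singular (condition number above 1e6) to
exercise the Cholesky clipping path.  Utility decrements default to
realistic magnitudes (MI 0.06, stroke 0.12, irregular heartbeat 0.05,
intermittent claudication 0.04, heart failure 0.10, ±10 % seed jitter);
post-event cost curves spike in the event year, fall within two years and
rise again with age.

The survey generator emulates a cross-sectional health survey of 7054
respondents: background utility by sex, age band and deprivation fifth,
minus flagged-event decrements, plus Gaussian noise (sd 0.1), clipped to
the SF-6D range.  The cohort generator simulates 16 000 individuals
exactly from the discrete-time equations (first events, post-event death,
subsequent-event flags) over a 21-year follow-up.  These feed the OLS and
probit recovery tests.  What the generators do **not** emulate: survey
non-response and sampling design, record-linkage artifacts, attrition,
measurement error in risk factors, cohort secular trends, and co-occurrence
of subsequent events.  Passing recovery tests therefore show the
estimators are correct for the stated model, not that the model fits any
real population.

Two oracles validate the KMSA engine:

* **Exact enumeration** (small horizons): plain-Python loops over every
  (first event, cycle) scenario and every post-event death time; the five
  subsequent-event indicators are independent of the death draws and enter
  the quality weight linearly, so each indicator's {0, 1} outcomes are
  summed exactly per cycle.  Agreement with the engine is at machine
  precision (asserted at 1e-10 relative).
* **Monte-Carlo microsimulation** (full horizon): 200 000 paths realising
  every draw as Bernoulli, scored with the same mid-cycle conventions and
  averaged; the engine must land within 3 standard errors.  The
  realised-path and expectation conventions coincide only while the
  utility floor is slack, which plain-mode magnitudes guarantee
  (minimum background 0.65 against a maximum total decrement ≈ 0.5);
  adversarial sets intentionally bind the floor and are excluded from
  oracle-agreement assertions.

## Numerical choices

* Probit link via `scipy.special.ndtr`; OLS and probit fitting delegate to
  statsmodels (Newton scoring; complete separation raised as an error).
* Restricted cubic splines use the truncated-power basis with the
  `(k_K − k_1)²` normalisation; predictors are exactly linear beyond the
  boundary knots (asserted by zero second differences).  Data-driven knots
  default to the {.05, .275, .5, .725, .95} quantiles.
* Cost predictions are floored at zero; costs are nominal, single
  price-year, no inflation indexing.
* Threshold analysis brackets and bisects (Brent) to 1e-6 relative; the
  cost-varying case is checked against its closed form in the tests.
* Root-finding for event-rate-to-risk-factor conversion is bounded by the
  factor's validity range and errors when the target is unreachable.
* Parameter-file round trips are bit-identical (`%.17g` on write,
  round-trip float parsing on read).

## Problem sizes used in the test suite

The suite runs the full 100-cycle engine against a 200 000-path
microsimulation for five parameter-set seeds, exact enumeration at horizon
10, and 20-seed recovery studies at the survey (n = 7054) and cohort
(n = 16 000) scales; the whole suite completes in about a minute on one
CPU.  `scripts/acceptance.py` repeats these end to end from a single seed.

## Known limitations

* Only hospitalisation costs are modelled: no primary-care, prescription,
  community, carer or productivity costs.
* SIMD is an input; the model does not compute it from its constituent
  domain indicators.
* SF-6D scores are consumed, never computed from questionnaire responses
  (the scoring algorithm is licensed); synthetic utilities are generated
  directly on that scale.
* No tunnel states beyond the two post-event states; a single post-event
  death equation per state (CVD and non-CVD death are not split after a
  first event).
* Subsequent events are independent per cycle; co-occurrence and
  accumulation of decrements are not modelled.
* Expected value of information analysis is out of scope in this version.
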
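# Methods

## The decision problem

Intertrochanteric hip fractures in the elderly are usually fixed with an
intramedullary nail (IMN) whose lag screw must sit within 20 mm of the
femoral-head apex (the "safe zone", tip–apex distance < 20 mm) to minimise
fixation failure. Optical navigation systems raise the share of screws
placed inside the safe zone (95.6% vs 74.0% freehand) but cost millions of
yuan to buy and maintain. The package asks, from a payer perspective in
2020 mainland-China prices: at what surgical volume, system price and
clinical performance does navigated IMN deliver an extra quality-adjusted
life-year (QALY) for less than the willingness-to-pay (WTP) threshold of
¥140,000/QALY?

## Cohort model

A Markov cohort of 70-year-old patients moves through four states in
annual cycles over a 5-year horizon:

* `SAFE_FIX` — successful fixation, screw inside the safe zone;
* `UNSAFE_FIX` — successful fixation, screw outside the safe zone;
* `SALVAGE_THA` — converted to total hip arthroplasty (THA) after
  fixation failure; assumed never to fail again within the horizon;
* `DEAD` — absorbing.

Cycle 0 is the index surgery: a fraction `p_periop = 6%` dies
perioperatively and survivors split between the fixation states with
probability `p_safe` (0.956 navigated, 0.74 freehand). Each later cycle
applies, in order:

1. **background death** — first-postoperative-year mortality (20%,
   interpreted as *including* the perioperative deaths, so the cycle-1
   conditional probability is (0.20 − 0.06)/0.94 ≈ 14.9%) for fixation
   states in cycle 1; age-specific mortality `q(age)` afterwards and for
   the salvage state throughout;
2. **fixation failure** among survivors — 2.7%/year inside the safe zone,
   7.5%/year outside (the latter derived from the inside rate and a pooled
   odds ratio of 2.94 via `p₁ = OR·p₀ / (1 − p₀ + OR·p₀)`). Failures
   undergo salvage THA: 6% die perioperatively; all incur the THA cost
   (¥108,000) and survivors a one-time disutility of −0.15 QALY;
3. **utility accrual** — fixation states earn the arm's annual utility
   (0.82 navigated, 0.79 freehand, from Harris Hip Scores 86.7/82.7
   through a linear score→utility map), the salvage state 0.6.

Both arms share all mortality and failure probabilities (the only arm
differences are `p_safe`, the fixation utility, and the navigation cost),
so any QALY gain comes from zone allocation and the utility gap.

## Conventions and calibration

Decision-tree software leaves several cycle-arithmetic choices to the
analyst, and the source publication reports only its outputs. We encode
the free choices as a discrete `ModelConventions` grid — whether first-year
mortality subsumes the perioperative deaths; utility accrual at cycle
start, cycle end (with a 0/0.5/1 fraction for decedents), or the
half-cycle trapezoid; whether fixation failure is possible in the first
postoperative year or only from year 2; whether effectiveness is
discounted — and cross it with a flat background mortality `q`. Each of
the 40 configurations is scored (after optimising `q` by coarse scan plus
bounded Brent refinement) by the sum of squared relative errors against
the published reference-case anchors: cumulative QALYs 3.32/3.18 and
salvage incidences 8.5%/11.1% for the navigated/traditional arms. The
salvage anchors are included because the QALY pair alone cannot identify
the failure-onset convention; calibration fails loudly (with the full
residual table) if no configuration reproduces both QALY anchors within
2%.

The fitted configuration is: first-year mortality includes perioperative
deaths; start-of-cycle utility accrual; failures from cycle 2;
effectiveness undiscounted, costs discounted at 3% from the first cycle;
`q = 0.0177` (a plausible annual death probability around age 70 for the
census table the source cites but does not reproduce). Residuals: QALYs
−1.2%/−1.0%, salvage −0.1%/+1.0%. Two findings forced this design:

* with discounted effectiveness no convention combination exceeds ≈3.25
  QALYs under the stated mortalities, so the published 3.32/3.18 can only
  have been produced with undiscounted effectiveness;
* the published per-arm outputs are not mutually consistent: the printed
  costs and ICERs imply an incremental effectiveness of 0.140 QALY and a
  larger salvage gap than the printed salvage rates allow (our calibrated
  increment is 0.132). No parameterisation of this model family can emit
  every printed number simultaneously; the chosen fit reproduces the
  traditional-arm cost, both salvage rates, and the ICERs at volumes
  100/200/300 within 2%, at the price of the safe-zone probability
  threshold (57.7% here vs the published 67.3%), which is only consistent
  with failure dynamics that would break the other outputs by 6–40%.

**Capital-cost allocation.** The per-patient navigation cost is
`(purchase/amortization_years + 5% · purchase) / annual_volume`. The
amortization period is backed out of the published navigated-arm total
cost (¥74,963 at volume 200) after the conventions are fixed, giving 3.21
years — i.e. the source charged the system more heavily than 5-year
straight-line amortization would. It is reported, not hidden, and a user
can override it.

## Outcome measures

For each arm: total discounted cost (index surgery plus discounted THA
costs), total effectiveness (sum of per-cycle accruals, undiscounted under
the calibrated conventions), and the undiscounted cumulative incidence of
salvage THA. Comparisons report Δcost, ΔQALY, ICER = Δcost/ΔQALY (only in
the costlier-and-better quadrant; dominance flags otherwise), net monetary
benefit NMB = WTP·ΔQALY − Δcost, and the relative salvage reduction.
Cost-effectiveness is decided by NMB ≥ 0, which coincides with ICER ≤ WTP
whenever the ratio is meaningful.

## Sensitivity analyses

* **ICER vs volume** follows the closed form `ICER(V) = A + B/V` exactly,
  because only the navigation allocation depends on volume; `A` and `B`
  are computed from one cohort run per arm with the system costed at zero,
  and the direct per-volume runs are checked against the closed form to
  1e-9 relative.
* **One-way analyses** perturb a parameter over ±50% of its base value
  (clipped to its domain) and classify the ICER relationship by the
  least-squares slope sign, calling it *flat* when the relative ICER
  spread is under 10%. The consequential parameters move the ICER by
  ≥19% over these ranges; the salvage disutility and perioperative
  mortality move it by ≤6%, so the 10% cut separates the two groups
  cleanly. Two derivation links are honoured: the salvage THA cost is
  twice the IMN procedure cost (so varying one carries the other, without
  which the IMN-cost relationship would be exactly flat rather than
  negative), and maintenance is a fraction of the purchase price.
* **Threshold searches** solve NMB(x) = 0 with Brent's method after a
  9-point monotonicity check, returning a no-solution sentinel when the
  NMB does not change sign over the bracket (e.g. the safe-zone
  probability at a 100-case volume, where navigation cannot become
  cost-effective even at 100% safe placement). Solutions satisfy
  |ICER − WTP| < ¥1/QALY.
* **Two-way maps** classify a price × safe-zone-probability grid by NMB
  sign at fixed volume; the cost-effective region is monotone in both
  axes.

## Probabilistic sensitivity analysis

1,000 Monte-Carlo samples draw the nine uncertain parameters
independently from the published distributions — Beta for probabilities
and utilities, Gamma (shape, *rate*) for costs; SDs are 10% of the mean
except the empirically known IMN-cost SD of ¥37,000. The published shape
parameters are used verbatim; method-of-moments refits of the printed
means/SDs reproduce them within ~1–3% for every row except the THA
utility, whose printed Beta(3999.4, 2666.3) implies an SD ten-fold below
its printed 0.06 (a decimal slip; both readings are available and change
the acceptance fraction by <0.2 points). Within a sample, draws common to
both arms are shared. The summary ICER is the ratio of means (the mean-of-
ratios variant is also exposed); the acceptability curve re-uses one
sample set across the WTP grid. Mortalities, the discount rate, WTP and
the system price are not sampled, matching the published table.

With these inputs the model reproduces the published acceptance at the
low volume (47–48% vs 48.4%) but sits ≈4.5 points below it at the medium
and high volumes (≈56% vs 60.4%, ≈59% vs 63.3%). The incremental-NMB noise
is dominated by the two fixation-utility distributions (SD 0.082/0.079
acting on ≈4.1 person-years); reproducing the higher published acceptance
would require roughly half that dispersion, and the source does not state
how its tool truncated or correlated the utility draws. The discrepancy
is reported as-is.

## Synthetic data

Property-based tests run on randomized scenarios: every scalar parameter
drawn uniformly within ±50% of its base (ordering of the failure rates
enforced), and Gompertz life tables `q(age) = min(1, q₀·e^{s·(age−a₀)})`
with `q₀ ∈ [0.005, 0.05]` and slope `s ∈ [0, 0.12]` — the standard shape
of adult human mortality. These emulate plausible inputs, not any specific
population: passing tests show the engine's invariants (occupancy
conservation, monotonicity, cohort–microsimulation agreement) hold across
the input space, They say nothing about how closely the synthetic
scenarios match real Chinese census mortality, which the flat calibrated
`q` stands in for.

## Verification

An individual-level microsimulation replays the identical event sequence
patient by patient with pseudo-random draws and must agree with the
cohort engine within 3 Monte-Carlo standard errors on cost, effectiveness
and salvage incidence at 10⁶ patients (and exactly when all probabilities
are 0/1). Calibration applied to anchors generated by the engine itself
recovers the generating convention tuple exactly and the mortality level
to 1e-4. All randomness flows through seeded `numpy` generators; equal
seeds give bit-identical results.

## Problem sizes and numerical choices

Default runs use the 5-cycle horizon, a 40-configuration × ~70-point
calibration grid (seconds), 1,000-sample PSAs (sub-second each; the
acceptance script averages twenty replicates), and a 10⁶-patient
microsimulation in the deepest verification test (~2 s). Brent threshold
solves use a relative bracket tolerance of 1e-10; state-occupancy sums are
enforced to 1e-12. Degenerate inputs fail loudly: probabilities outside
[0, 1], infeasible Beta moments (sd² ≥ mean(1−mean)), zero volumes or
amortization periods, equal QALY anchors, and cost anchors below the
clinical cost all raise typed errors rather than propagating silently.

## Known limitations

* The horizon is 5 years; no lifetime extrapolation, no re-revision of the
  salvage THA, no alternative salvage pathways, no sex-stratified
  mortality.
* The background-mortality stand-in is a single flat `q` resolved by
  calibration; a real life table can be supplied as `age,qx` CSV and
  bypasses that knob.
* The capital-cost allocation is a modelling reconstruction; the published
  high-volume price threshold (¥12,624,617) is inconsistent with *any*
  per-case allocation (1.5 × the medium-volume threshold would be
  ¥17.5M) and is flagged rather than reproduced.
* Published outputs constrain but do not uniquely determine the source's
  decision-software implementation; the residual discrepancies quantified
  above (safe-zone threshold, medium/high-volume PSA acceptance) are the
  irreducible remainder.
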
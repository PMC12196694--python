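# Methods

## Model structure and assumptions

The cohort model has four health states — the WHO immunological strata
of CD4 counts (<200, 200–349, 350–499, ≥500 cells/μL) — and annual
cycles over a five-year horizon. Transition matrices are year-specific
for years 1–3; years 4 and 5 reuse the year-3 matrix (the
carry-forward assumption, reflecting thin data beyond three years of
follow-up). There is no death state: the modelled population is in
outpatient care with near-universal viral suppression, and five-year
HIV-specific mortality under effective ART is small relative to the
transition probabilities being modelled. The engine nevertheless
handles absorbing rows (unit-vector rows) without special-casing; the
state space itself is fixed at four.

Stage intervals are half-open on the left: a count of exactly 200
falls in 200–349 and exactly 500 in ≥500.

## Accrual and discounting convention

Costs and utilities are evaluated at the six model times t = 0..5
(the baseline state plus the five post-transition states), each
discounted by (1+r)^−t with r = 5 %/year for both costs and benefits.
*Initial* stage costs (first year of care) accrue only at t = 0,
undiscounted; *incremental* stage costs (subsequent years) accrue at
t = 1..5. No half-cycle correction is applied, and the convention is
exposed as a single enumeration value (`EVAL_AT_STAGE_START`) so that
alternatives could be added without changing call sites.

This convention is a deliberate design choice: the printed cumulative
effectiveness of 3.80 QALYs is only reachable with six evaluation
points (any five-point convention is bounded by 5 × 0.73 = 3.65), and
with it the package reproduces the published totals to within the
rounding of the printed inputs (computed: USD 8,433.70, 3.7964 QALYs,
USD 2,221.48/QALY against printed 8,431.95 / 3.80 / 2,218.93).

## Input normalization

Printed probability tables round independently, so rows can sum to
0.99–1.01. Every probability vector and matrix row is divided by its
sum at load time; the engine warns when the deviation from 1 exceeds
0.02 and errors above 0.05 (the packaged-fixture loader warns already
at 0.005, so the three rounded published rows are reported). Post-
normalization stochasticity is enforced to 1e-9.

A known consequence: straightforward arithmetic on the renormalized
matrices puts 67.9 % of the cohort in CD4 ≥ 500 at year 5 (63.1 % at
year 4), whereas the source narrative reports "more than 70 %". The
package reports the computed trace and does not force agreement; the
figure's provenance (evaluation point, unnormalized rows, or a
microsimulation) is not stated in the source.

## Costing

Stage-year costs follow `Σ UC_i × F_i × P_i` over resource line items
(unit cost × annual frequency of use × proportion of patients using
the resource), converted to USD at 18.22 MXN/USD. Because the
resource-level workbook behind the published stage totals is not
available, the packaged fixture carries the totals directly
(*direct mode*); *line-item mode* implements the equation for users
with their own resource tables. `decompose_schedule_with_drug` splits
each stage total into the ART drug component (USD 94.40/month × 12)
plus a residual services item, which reproduces the totals exactly
while making the drug price a single named handle for sensitivity
analysis. Money is floating point internally and reported to 2
decimals at I/O boundaries; discounting lives in the Markov engine
only.

## Transition estimation

Year-specific matrices are maximum-likelihood multinomial row
proportions of observed consecutive-year stage pairs. Pairs spanning a
gap are skipped — no interpolation or imputation, since visit-spacing
handling in the source derivation is undocumented and
consecutive-pair counting is the least-assumption choice. An optional
Laplace pseudo-count supports sparse panels; a zero row with zero
smoothing falls back to "remain in stage" (identity row) with a
warning. Estimated matrices are row-stochastic by construction.

## Sensitivity analysis

The probabilistic analysis perturbs **every** scalar input — unit
costs (or stage-cost cells when no resource table is attached),
utilities, baseline probabilities, and all transition-matrix entries —
by independent Uniform[1−v, 1+v] multipliers with v = 0.07. No
distributional family is prescribed by the source beyond "a variation
of 7 %", so the uniform family is the documented default (an
enumeration point, extensible). Utilities are clamped to [0, 1] and may
instead be drawn from explicit per-stage ranges; baseline vectors and
matrix rows are renormalized after perturbation (simplest construction
that keeps every draw a valid model; logit-space perturbation was
considered and rejected as an undocumented stronger assumption). All
draws flow through a single seeded generator: identical configuration
gives bit-identical results. At 10,000 iterations the analysis runs in
a few seconds; with symmetric multiplicative noise the sample means
sit within Monte Carlo error of the base case and every cost-per-QALY
draw stays below the WTP threshold.

The tornado analysis moves one named scalar at a time to (1−v)× and
(1+v)×, renormalizing any affected probability structure, and reports
the larger absolute swing in total cost as a percent of the base case.
A parameter multiplying the entire cost schedule therefore has impact
exactly v; the drug line item, present in every stage-year cost at
USD 1,132.80/year, has impact ≈5 % at v = 7 %. The published impacts
for medical visits, viral-load and CD4 studies depend on the
unavailable resource-level workbook and are out of scope.

## Synthetic cohort generator

The generator emulates the modelled clinic population: default
n = 237 ART-naive patients, baseline stage mix (0.39, 0.22, 0.16,
0.23), stage paths drawn from the year-specific matrices with year-3
carry-forward, 95.4 % viral undetectability (<50 copies/mL; detectable
loads uniform on [50, 10,000]), adherence index Normal(89.97, 11.98²)
truncated (clipped) to [0, 100], age Normal(35.74, 9.43²) floored at
18, and gender drawn 88.9/7.7/3.4 % male/female/transgender female.
CD4 counts are uniform within the occupied stage's bin, capped at
1,500 cells/μL for the open-ended stratum — only stage occupancy is
specified by the study conditions, so the within-bin law is the
least-assumption choice and every generated count classifies back into
its generating stage. Clipping (rather than rejection sampling) for
the adherence truncation keeps determinism trivial; it pulls the
sample mean ~1.3 points below the nominal mean, which the descriptive
tests allow for. Optional per-year dropout truncates trajectories;
`degrade_panel` deletes non-baseline observations independently to
exercise gap handling.

What the generator does **not** emulate: ART regimen switches,
within-year CD4 kinetics, correlation between adherence and
virological or immunological outcomes, questionnaire item-level
responses, and irregular visit spacing. Passing recovery tests
therefore show that the estimators invert the generator's multinomial
panel process, not that they are robust to the messiness of real
clinic extracts.

## Other calculators

- Sample size: n = ceil(z² p(1−p)/d²); p = 0.79, 95 % confidence,
  5 % margin gives 255. Symmetric in p ↔ 1−p, maximized at p = 0.5;
  degenerate p ∈ {0, 1} returns 0 with a warning.
- Viral-load boundary: exactly 50 copies/mL is classed unsuppressed
  (the published category labels are exhaustive: undetectable <50,
  unsuppressed ≥50).
- Budget projection: per-person annual cost = cumulative model cost /
  horizon; the clinic series is exactly geometric in the 12.1 % annual
  caseload growth. At 21,749 clients the year-0 total is USD 36.68 M;
  compounding five years gives USD 64.94 M, about 0.3 % above the
  published "USD 64.75 M by 2029" (whose compounding base is
  unstated) — the computed series is reported as-is.

## Verification strategy and problem sizes

The cohort trace is cross-checked against an independent
per-individual microsimulation (categorical path sampling) at 200,000
individuals, agreeing within three standard errors estimated from
replicate runs. Transition estimation is validated by
generator/estimator round trips at panel sizes 500 / 5,000 / 50,000
(maximum absolute error below 0.01 at the largest size); per-cell
errors are checked against binomial 3σ envelopes, which is the
calibrated bound for sparse origin stages (the <200 row at year 3
carries only ~6 % of the cohort). Property-based tests cover occupancy
conservation, discount monotonicity, and the zero-discount closed
forms on randomized row-stochastic inputs. These sizes keep the full
suite under a minute on one core while leaving every stochastic check
at 3σ or better.

## Known limitations

- Non-comparative: the ratio is cost per QALY of the programme itself,
  not an incremental ratio against an alternative.
- No death state, no lifetime horizon, no half-cycle correction, no
  inflation adjustment, no indirect or opportunistic-infection costs.
- Line-item costing cannot be validated against the original
  resource-level workbook (unavailable); only the direct stage totals
  are packaged.
- Transition matrices are estimated from at most three years of
  observed pairs and assumed stationary thereafter.
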
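# Methods

## Model and assumptions

The analysis treats calorie production of the major cereals as a separable
function of per-(unit, crop) uniform synthetic-fertilizer rates.  Each grid
cell (pixel × crop × water regime × crop model) carries a cubic polynomial
mapping total nitrogen `t` (kg/ha, fertilizer plus biological fixation) to
yield (t DM/ha), valid on `t ∈ [0, 200]` and clamped at zero.  Yields are
converted to calories with crop-specific energy densities (4.05 Gcal/t DM
maize, 3.22 rice, 3.68 winter wheat, 3.80 spring wheat) and aggregated to
administrative units as harvested-area-weighted means.  Because every
member pixel of a unit receives the same rate, unit-level aggregation is
exactly equivalent to pixel-level accounting (tested to 1e-10 relative);
what is lost, deliberately, is within-unit reallocation — the same
restriction the underlying data impose, since within-country fertilizer
distributions are not observed.

Ensemble handling: the six crop-model coefficient sets are averaged with
equal weight pixel by pixel to form the ensemble-mean response; model
ranges are obtained by re-optimizing per model (evaluating the
ensemble-optimal allocation under each model is also implemented).
Averaging calorie responses versus yields is immaterial because the
calorie conversion is linear within crop.

Scenario budgets are **total nitrogen** (fertilizer + biological
fixation).  Only fertilizer is reallocated, so the optimizer's fertilizer
budget is the scenario budget minus the global fixation total, and rice's
total-N bounds (33–200 kg/ha) translate into fertilizer bounds
`[max(0, 33 − b_u), 200 − b_u]` for a unit with fixation rate `b_u`.

## Optimization

Both problems — maximize production under a budget, minimize input under a
production floor — are separable with a single coupling constraint.  When
every unit response is concave and non-decreasing on its feasible interval
(checked explicitly, per unit, from the aggregated cubic), the solver uses
the dual structure directly: for a shadow price λ each unit's rate is the
unique point where its marginal calorie product equals λ (clipped to
bounds), and λ is bisected until the budget (or floor) binds.  This is
deterministic, runs in milliseconds at 800 decision variables, lands on
the feasible side of the constraint by construction, and satisfies the
equimarginal KKT conditions to the bisection tolerance (≈1e-12 relative on
the constraint).  Initialization is irrelevant on this path because the
concave optimum is unique.

If any response fails the concavity check (possible with
`allow_nonmonotone` emulator-style tails), the solver falls back to SLSQP
on rates normalized to [0, 1], with analytic gradients, initialized from
the current allocation rescaled onto the budget; correctness in that
regime rests on the oracle tests, not on solver identity.  A returned
allocation below the initial point's objective is flagged unconverged.

The KKT report classifies each (unit, crop) as interior or bound-active
(relative tolerance 1e-6 on the rate span) and checks interior marginals
against the shadow price at 1e-3 relative tolerance, with one-sided checks
at the bounds.  It is skipped, with a logged notice, for non-concave sets.

Independent oracles in the test suite: a dynamic program over the 1 kg/ha
rate grid with integer-kg budget states (an exact equivalent of exhaustive
grid enumeration for separable objectives), full 2-unit grid enumeration
for minimum input, and the closed-form equimarginal solution for quadratic
instances.

## Reference distributions

*Current*: the world's current rates, passed through with bounds checks.
*Equal*: one common total-N rate per crop chosen so the crop's budget is
met exactly; units whose bounds clamp the common rate are logged, and the
residual is water-filled back onto the unclamped units, so conservation is
exact whenever the target is within the feasible range (targets at or
beyond the range saturate at the bounds with a logged residual).
*Equal relative reduction*: every unit's current fertilizer rate scaled by
one factor per crop toward the target, then clamped; the clamping residual
is logged but not redistributed, since this reference is defined by the
common factor, not by conservation.  With the real national totals the
equal reference corresponds to 119 kg/ha maize, 160 rice, 100 winter
wheat, 75 spring wheat; reproducing those exact rates requires the
external datasets and is therefore documented here rather than unit-tested.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes:

- **Responses**: scaled saturating templates
  `y(t) = Y · (y₀ + (1 − y₀)(1 − exp(−k t)))` fitted by least squares with
  cubics on [0, 200] kg/ha (41 points).  Keeping `k ≤ 0.0095` per kg/ha
  makes every fitted cubic monotone non-decreasing *and* concave on the
  domain; `allow_nonmonotone` widens `k` to 0.025, producing the slightly
  non-monotone, non-concave tails typical of unconstrained polynomial
  emulator fits.  Plateaus are 10/8/7/5 t DM/ha (maize/rice/winter/spring
  wheat) with mean `k` of 0.0085/0.0091/0.0078/0.0078 — half-saturation
  near 75–90 kg N/ha.
- **Heterogeneity**: log-normal multiplicative plateau factors per unit
  (σ = `response_heterogeneity`, default 0.15) and per pixel (σ/2),
  regime multipliers 0.9 (rainfed) / 1.15 (irrigated), narrow spreads on
  `k` (σ = 0.08) and the zero-N intercept.  These defaults keep the
  cross-unit spread of aggregated responses moderate, reflecting that
  national aggregation averages out local extremes; they reproduce the
  qualitative pattern seen in the real data that a uniform per-crop rate
  is near-optimal.  Larger spreads make tailored allocation pull further
  ahead of the equal reference.
- **Model ensemble**: each model's coefficients are the shared base curve
  times a log-normal factor (global per-model bias plus per-cell noise,
  σ = 0.08, mean one), so an ensemble mean exists by construction.
- **Current allocation**: a latent unit wealth drives GDP (log-normal),
  food insecurity (logistic-transformed, right-skewed, in (0, 100)), and
  raw fertilizer rates `∝ exp(input_skew · wealth)`.  Rates are scaled
  onto the configured global fertilizer total (default 54 Tg/a — a
  59 Tg/a crop total less 5 Tg/a rice fixation) by a bounded proportional
  multiplier with the clipping residual spread over unclipped units, so
  the total is met to machine precision and all bounds hold.  At
  `input_skew = 0` the input–insecurity correlation is below 0.2 in
  magnitude (checked over 100 seeds at 200 units); at 2.0 it is strongly
  negative (≈ −0.75).
- **Areas**: 5.4e8 ha split 30/29/26/15% across crops, log-normal unit and
  pixel weights, irrigated share per unit Beta(6, 12).
- **Rice fixation**: per-unit rates drawn U(20, 40) kg/ha and rescaled so
  the global rice fixation total is exactly 5 Tg/a; uniform within a unit.

What the generator does **not** emulate: real geography and climate
forcing, correlations between wealth and biophysical productivity, crop
calendars, trade, or the actual archive of emulator coefficients.  Passing
tests therefore demonstrate the correctness and the qualitative behavior
of the machinery on data with the assumed structure, not the real-world
magnitudes, which depend on the deposited external datasets.

## Statistics

Nitrogen quantities are regressed on natural-log food-insecurity
prevalence (the quantity as response, log prevalence as regressor; slope
magnitudes are log-base-dependent, so comparisons with results on other
bases require conversion).  Pearson's r, the OLS slope with 95% CI and
P-value, and the post-omission n are reported.  Outlier omission replaces
plot-based judgment with a deterministic rule: iteratively drop the
largest-Cook's-distance observation that both exceeds the 4/n screen and
fails a Bonferroni-corrected externally-studentized-residual test at the
5% family level, refitting after each drop, at most three drops.  The
Bonferroni confirmation is what keeps clean samples untouched — a bare
4/n threshold flags a handful of points in any well-behaved sample.  On
planted 10-σ outliers the rule recovers the planted point in ≥95% of
seeds; 95% CI coverage of a planted slope is 90–99% over 500 seeds.

## Numerical choices and problem sizes

kg, ha and Gcal internally; Tg (1e9 kg) and Pcal (1e6 Gcal) only at I/O.
Polynomial yields are clamped at zero before calorie conversion.  Dual
bisection: 200 iterations on λ, 60 on each rate; conservation helpers use
`brentq` to 1e-12.  Ties among identical units resolve identically by
construction (the same λ maps to the same rate); ordering is stable by
(unit, crop).  Worlds are serialized as NetCDF-3 (scipy backend) plus CSV
and key=value config, round-tripping bit-exactly for float64.

Test and demonstration runs use worlds of 12–200 units, 4 pixels per unit,
4 crops, 2 regimes and 6 models (up to ~38k grid cells, 800 decision
variables); the acceptance script uses 200 units.  These sizes exercise
every code path at full ensemble width while a full run stays under a
minute.

## Known limitations

- No within-unit reallocation (by design, mirroring the data limitation).
- The dual fast path requires concavity; strongly non-concave ensembles
  fall back to SLSQP, which at this problem scale is slower and, like any
  local NLP method, not certified global.
- The equal-relative-reduction reference can exceed its nominal budget
  when lower bounds clamp scaled-down rates; the residual is reported,
  never silently absorbed.
- Synthetic-world percentages (e.g. the ~7–12% reallocation gain) are
  analogs whose exact values depend on generator settings; only their
  qualitative ordering and the machinery's exactness properties are
  asserted.
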
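# Methods

## Model structure and assumptions

The simulator treats food demand as the outcome of a causal chain from
socio-economic development to anthropometrics to energy flows.  Per-capita
income is the single behavioural driver; it proxies aggregate development,
not household income.  The chain within each 5-year timestep is:

1. **Height.** The 15–19 cohort's height is `H = α_s G^β_s`, where the
   diet-quality driver `G` is the sum of animal-source and empty calories
   per capita, averaged over the three preceding timesteps (roughly the
   pre-natal to age-14 window of that cohort).  Adult cohorts carry their
   height forward unchanged as they age; the open 100+ cohort takes the
   height of the incoming 95–99 cohort.  Child cohort heights are the
   bundled growth-standard curve scaled by the factor by which the current
   15–19 cohort diverges from the standard's 18-year height.
2. **BMI distribution.** Population shares of six adult BMI classes
   (<18.5, 18.5–20, 20–25, 25–30, 30–35, ≥35 kg/m², representative values
   17.5 … 37.5 by the midpoint convention, open tails as 5-unit classes)
   and five child classes in growth-standard SD units (representative
   z = −2.5, −1.5, 0, 1.5, 2.5) follow per-class saturating curves in
   income, `s_b(Y) = c_b + d_b·Y/(k_b + Y)`, clipped to [0, 1] and
   renormalized to a proper distribution.  The saturating form encodes the
   assumption that overweight/obesity prevalence saturates at very high
   income; `d_b` may be negative for classes that shrink with development.
3. **Energy requirement.** Body weight is `W = B·(H/100)²` per class; child
   representative BMI is `median_bmi + z·bmi_sd` at the cohort midpoint
   age.  BMR is the weight-based Schofield linear form per age bracket and
   sex, multiplied by a physical activity level `A` that mixes a sedentary
   (1.53) and an active (1.76) multiplier — the FAO/WHO/UNU category
   midpoints — with an income-saturating inactivity share per age group and
   sex (children's share is income-flat by default; inactivity is higher in
   the 60+ group).  Steady-state intake equals expenditure; country intake
   is the population- and share-weighted mean plus a pregnancy/lactation
   add-on of N = 460 kcal/day sustained for one year per newborn,
   `N·P₀₋₄/5` per 5-year cohort, expressed per capita.
4. **Waste and demand.** Demand (FAOSTAT-style availability) is intake
   times `1 + εY/(ζ+Y)`; waste is the difference, so waste is zero at zero
   income and saturates at a fraction ε of intake.
5. **Composition.** Demand is split by a nested tree — animal first, then
   empty calories from the plant remainder, then fruits/vegetables/nuts,
   staples as the residual — with each split share saturating in income.
   The nesting guarantees the four groups sum to total demand exactly.
   No allowance is made for a declining animal share at very high incomes;
   the saturating form is deliberately conservative there.

Since the model's composition output does not separate pulses (inside
staples) or oils (inside empty calories), the height driver `G` is defined
as animal + empty calories.  This proxy is used identically in simulation
and fitting, so it introduces no internal inconsistency.

At the first simulated year no `G` history exists.  The engine solves the
within-year fixed point — `G` equals the composition the model itself
produces that year — by deterministic iteration from growth-standard
heights (converges to 1e-13 in a handful of steps).  The fitting code uses
the matching convention (contemporaneous observed `G` at the panel start),
which keeps simulate-then-refit exact.

## Parameters

| Block | Form | Defaults (synthetic truth) |
|---|---|---|
| Height | `α_s G^β_s` | α = 116 (m) / 107 (f) cm, β = 0.06 |
| BMI shares | `c + d·Y/(k+Y)` per class/age group/sex | per-stratum tables in `parameters.default_parameters`; k = 7,000–10,000 USD |
| Waste | `1 + εY/(ζ+Y)` | ε = 0.5, ζ = 10,000 USD |
| Diet tree | `a·Y/(b+Y)` per level | animal (0.35; 10,000), empty (0.35; 8,000), fruit/veg/nut (0.25; 6,000) |
| PAL | inactivity `c + d·Y/(k+Y)`, mix of 1.53/1.76 | working adults 0.10–0.15 → +0.35, 60+ 0.25–0.30 → +0.40–0.45, children flat 0.20 |
| Pregnancy | N kcal/day per newborn-year | 460 |
| Schofield | `γW + δ` per bracket/sex | FAO/WHO/UNU weight-based table, shipped as CSV in kcal |

Incomes are USD2005 PPP per capita per year; all energy flows are
kcal/cap/day internally, converted to joules (1 kcal = 4184 J,
thermochemical) only at reporting boundaries, 365 days per year.  The
default BMI-share truth tables are constructed so the raw per-stratum
curves sum to exactly one at every income: clipping and renormalization are
then no-ops on clean data, which makes every class curve exactly
identifiable from generated panels.  Cohorts map to Schofield brackets by
midpoint age (e.g. 15–19 → bracket 10–18); the mapping and the coefficient
table are user-replaceable, as is the growth standard (the bundled table is
a stylized synthetic stand-in pinned to plausible magnitudes, not the
official WHO tables).

## Fitting

All saturating curves are fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`) wrapped in a scikit-learn-style estimator.
The driver is rescaled by its median — making the fit exactly
scale-equivariant — and the half-saturation constant is multi-started at
0.1×, 1× and 10× the median; the lowest residual sum of squares wins, ties
going to the smallest half-saturation.  Tolerances are tight (1e-13) so
noiseless synthetic data are recovered to near machine precision.  The
height power law is closed-form OLS in log–log space.  Observations are
equally weighted; population weighting is a deliberate non-default.
Flat responses are fitted as constants and flagged unidentifiable rather
than failing.

The end-to-end fit proceeds in causal order: diet tree and height from
observed panels alone; BMI-share curves from observed shares against
income; the waste curve last, as observed demand over the intake implied by
the freshly fitted anthropometric chain (with `G` taken from observed
composition).  PAL parameters and N are configuration, not fitted — the
kind of quantity that in practice comes from survey data rather than the
demand panel.

Cross-validation partitions countries (never years) into k seeded folds;
for each fold the model is refitted on the training countries and run
forward, uncalibrated, for the held-out countries, scoring out-of-sample R²
at an evaluation year (default 2010) for four indicators: height, BMI
shares, per-capita demand and composition.

## Calibration

Additive calibration derives offsets (reported − raw model value) at every
reported cell, sequentially within a calibrated pass in pipeline order —
height, BMI shares, demand, composition — because each variable's raw value
depends on upstream calibrated ones.  At derived cells the calibrated value
is stored and applied as the reported value itself, which is the
bitwise-exact form of `raw + (reported − raw)`; at other years the stored
offsets apply, forward-filled (held constant beyond the last reported
year).  Backfilling the earliest factors into pre-data years — the
convention for early BMI data — is available behind a flag and documented
as approximate.  Calibrated values are cut off below zero, shares above
one, and demand below intake (so waste stays non-negative); every cutoff is
logged with variable, year and cell count, and share blocks are only
renormalized when a cutoff actually moved their sum.

## Counterfactuals and decomposition

Counterfactuals re-evaluate one year of a finished run with a single switch:
moving underweight (or overweight) class mass into the 20–25 kg/m² class
(children: the −1…+1 SD class) — the normal-weight reference — setting the
activity multiplier to the active value, or setting demand equal to intake.
The zero-waste change is algebraically −100·X/D.  Any additive demand
calibration is preserved by shifting demand with the modeled waste response
to the intake change.

Demand growth between two timesteps is decomposed by chained sequential
substitution in the fixed order population → requirements (age–sex
structure and height) → BMI → PAL → waste → composition (the last only
matters for animal-source demand).  The contribution of factor i is the
total when factors 1…i are at their end state minus the total when 1…i−1
are; contributions therefore sum to net growth exactly, and order
sensitivity is quantified by also reporting the reversed order rather than
hidden behind an averaging scheme.

## Synthetic worlds

The generator produces the study conditions under which the machinery is
validated: 30 countries by default, incomes following logistic growth
between country-specific floors (500–2,000 USD) and ceilings
(5,000–60,000 USD, log-uniform) — a range wide enough to identify every
half-saturation constant (a narrow income range leaves half-saturations
weakly identified) — and a cohort-component population with
income-declining fertility and Gompertz-type mortality, which reproduces
the demographic transition from young pyramids to ageing societies.  All
randomness flows from a single seed.

Observation noise (all seeded, chosen once as plausible magnitudes for
smoothed international panels): multiplicative log-normal with σ = 0.01 on
height; Gaussian σ = 0.03 on BMI-share logits with renormalization;
multiplicative log-normal σ = 0.05 on the waste margin X — applied to the
margin rather than demand so reported demand never falls below intake —
and Gaussian σ = 0.05 on the diet-tree share logits, with composition
reconstructed from the noisy demand so the four groups still sum exactly.
The generator targets statistical structure, not country realism: it
emulates smooth income growth, demographic ageing and income-driven
behavioural curves, but not business cycles, wars, migration, price shocks,
intra-country heterogeneity or time trends beyond income.  Passing tests
therefore demonstrate that the estimation and scenario machinery inverts
and conserves what the model generates — not that the model is a validated
description of any real country.

## Numerical choices and problem sizes

The engine is vectorized over countries with a single time loop;
a 30-country, 28-timestep run takes well under a second and repeated runs
are bit-identical.  Test and acceptance workloads use 12–30 country worlds,
50 noise replicates for the bias check and 10⁶ draws for the conservation
identities — sizes chosen so the whole suite runs in a few minutes on one
CPU while leaving the identities at full precision.  Degenerate inputs are
surfaced, not repaired: missing driver cells, demand/intake ratios below
one, zero populations, constant observations in R², non-positive values in
log fits and unmapped cohorts all raise with named locations.

## Known limitations

* Income is the only behavioural driver; urbanization, prices, education
  and time trends are absorbed into it, and obesity at high income is
  likely conservatively low given the saturating forms.
* The PAL construction and the child z→BMI mapping are documented stylized
  rules with the qualitative behaviour described above, not estimates from
  activity or growth-standard microdata.
* The bundled growth standard is synthetic; supply official tables for real
  applications.
* Backfilled calibration factors are approximate for the pre-data period.
* No commodity detail below the four groups, no nutrient accounting, no
  temperature-dependent metabolic variant (the coefficient table is
  pluggable), no spatial disaggregation below countries.
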
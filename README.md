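# fooddemand

A long-term food demand simulator for nutrition-transition research.  From
only two exogenous drivers — per-capita income `Y` and population by 5-year
age cohort and sex `P` — the model projects, in 5-year steps on a country
panel:

* **body height** of young adults and (via growth-standard scaling) children,
* the **BMI-class distribution** of the population,
* **food intake** from basal metabolic rates and physical activity,
* **household food waste** and total **food demand** (availability),
* the four-group **dietary composition** (animal-source, empty calories,
  fruits/vegetables/nuts, staples),

together with the machinery around such a model: regression fitting of every
behavioural parameter, additive calibration to reported data, k-fold
cross-validation by country, behavioural counterfactuals, a chained
decomposition of demand growth, and a synthetic-world generator so the whole
pipeline is testable without external downloads.

## The model

Anthropometrics come first.  Young-adult height follows a power law in the
diet-quality driver `G` (animal-source plus empty calories, averaged over the
three preceding timesteps), `H₁₅₋₁₉ = α_s G^β_s`; older cohorts keep their
height as they age.  Each BMI class `b` has a representative BMI `B`, giving
body weight `W = B·(H/100)²` and, through the Schofield equations and the
physical activity level `A`, a steady-state intake per class
`I = (γ_{a,s} W + δ_{a,s})·A`.  Class shares `S_b`, the activity level, the
waste markup and the diet-tree shares are all saturating functions of income
of the form `a·Y/(b+Y)` (+ offset):

```
D/I = 1 + εY/(ζ+Y)                     demand exceeds intake by waste X = D − I
L   = ηY/(θ+Y) · D                     animal calories
E   = ιY/(κ+Y) · (D − L)               empty calories (oils, sugar, alcohol)
V   = λY/(μ+Y) · (D − L − E)           fruits, vegetables, nuts
R   = D − L − E − V                    staples (residual, exact by nesting)
```

Country intake is the population- and share-weighted mean over cohorts, sexes
and BMI classes, plus a pregnancy/lactation add-on `N·P₀₋₄/5` per capita.

## Worked example

```python
import fooddemand as fd

spec = fd.WorldSpec(n_countries=30, seed=1)     # a synthetic world
drivers = fd.make_drivers(spec)
obs = fd.make_observations(drivers, spec.truth, noise=0)

fitted = fd.fit_parameters(drivers, obs)        # refit from the panels
result = fd.run_scenario(drivers, fitted)
agg = fd.global_aggregate(result)
```

On this world the fit recovers the generator's parameters (for example the
waste curve comes back as `epsilon=0.5000, zeta=10000.0` and male height as
`H = 116.0 · G^0.060`), and the projection prints:

```
1965: total demand  2.78 EJ/yr, animal share  9.6 %
2010: total demand  6.44 EJ/yr, animal share 18.5 %
2050: total demand  8.27 EJ/yr, animal share 21.3 %
```

i.e. total demand roughly triples while the animal-source share doubles as
the synthetic world moves through its nutrition transition.  The behavioural
counterfactuals at 2050 show the characteristic asymmetry — eliminating
underweight barely raises demand, while waste dominates the reduction
potential:

```
underweight_to_normal    +0.8 % of 2050 demand
overweight_to_normal     -7.8 % of 2050 demand
inactive_to_moderate     +4.9 % of 2050 demand
zero_waste              -22.9 % of 2050 demand
```

and the chained decomposition attributes 2010–2050 demand growth to
population (+1.13 EJ), rising requirements from ageing and height (+0.19),
BMI (+0.09), activity (−0.05) and waste (+0.47), summing exactly to the net.

The same workflow is available from the shell:

```
fooddemand synth --countries 30 --seed 1 -o world/
fooddemand fit world/
fooddemand project world/ --params world/params_fitted.json -o out/
fooddemand counterfactual world/ --params world/truth.json --switch zero_waste --year 2010
```

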
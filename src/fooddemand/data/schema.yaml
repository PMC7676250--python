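# Machine-readable schema for the long-format panel CSVs.
# All energy flows are kcal per capita per day; populations are persons;
# incomes are USD2005 PPP per capita per year.  Years are representative
# years of 5-year periods on the grid 1965, 1970, ..., 2100.  Missing data
# is an empty cell, never zero.
variables:
  income:
    unit: USD2005 PPP / capita / year
    dims: [country, year]
  population:
    unit: persons
    dims: [age, sex, country, year]
  height_cm:
    unit: cm
    dims: [sex, country, year]
    note: body height of the 15-19 age cohort
  bmi_share:
    unit: population share in [0, 1]
    dims: [bmi_class, agegroup, sex, country, year]
    note: shares sum to 1 over bmi_class within each stratum
  intake:
    unit: kcal / capita / day
    dims: [country, year]
  demand:
    unit: kcal / capita / day
    dims: [country, year]
    note: FAOSTAT-style availability; demand = intake + household waste
  waste:
    unit: kcal / capita / day
    dims: [country, year]
  animal_kcal: {unit: kcal / capita / day, dims: [country, year]}
  empty_kcal: {unit: kcal / capita / day, dims: [country, year]}
  fvn_kcal: {unit: kcal / capita / day, dims: [country, year]}
  staple_kcal: {unit: kcal / capita / day, dims: [country, year]}
index:
  year: {grid: [1965, 2100, 5]}
  age:
    cohorts: 20 five-year classes 0-4 .. 95-99 plus 100+
  sex: [male, female]
  agegroup: ["0-14", "15-59", "60+"]
  bmi_class:
    adult: ["<18.5", "18.5-20", "20-25", "25-30", "30-35", ">=35"]
    child: ["<-2SD", "-2SD:-1SD", "-1SD:+1SD", "+1SD:+2SD", ">+2SD"]
conventions:
  energy_to_joules: 4184.0   # J per kcal, applied only at reporting
  days_per_year: 365
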
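# hfcaresim

Discrete-event, patient-level simulation for comparing the health and cost
outcomes of **conventional** versus **telemedically supported** care of
chronic heart-failure patients, with reimbursement modelled after the
Austrian LDF/DRG case-flat-rate system.

The package is aimed at health economists and payer-side analysts who want
to explore budget impact, reimbursement strategies and break-even horizons
for telemonitoring programmes, at cohort sizes and time horizons beyond
what clinical studies cover.

## The model

Each simulated patient carries a NYHA severity class (1–4) and moves, in
one-day time steps, between two blocks:

* **Outpatient care.** In the conventional arm, every day a patient's
  condition may worsen (probability `w` per day). A worsening escalates to
  an emergency admission (probability `e`) or to a response: a medication
  change without personal contact, or a contact with a general
  practitioner, specialist, or ambulance. If the contact does not improve
  the condition (probability `1 − i`), the patient may die extramurally,
  be referred to hospital (probability `r`), or carry over to the next
  day. In the telemedical arm, patients transmit vital data daily and the
  branching happens in a **weekly control cycle**: an alarm can trigger an
  emergency, a successful remote intervention, or a face-to-face contact
  (home visit / doctor visit / hospitalisation) with a subsequent
  adaptation check. Routine GP/specialist visits arrive independently as
  Poisson processes at per-year rates.
* **Inpatient care** (identical in both arms): ICU involvement, ward and
  ICU lengths of stay (log-normal around class-specific medians),
  individual medical procedures (IMPs), in-hospital mortality, and a
  post-discharge NYHA transition (improve / stay / worsen by one class).

Costs: outpatient events are priced at fixed tariffs; a hospital stay of
`L` days earns the LDF flat score `F` if `L` lies within the trim points
(4–12 days for heart failure), `F + (L − 12)·s` beyond the upper trim
point, and a reduced flat rate below the lower one; ICU days earn a daily
supplementary score; IMPs add their catalogue points. Points convert to
euros by an adjustable factor. Telemonitoring is financed either as a flat
monthly rate per patient (variant A) or as acquisition + monthly overhead
+ per-patient physician fee (variant B). All accounting is in integer euro
cents.

Published study inputs drive daily behaviour through a hazard conversion:
a per-period admission probability `p` over `T` days maps to the daily
hazard `h` with `1 − (1 − h)^T = p`, which is then apportioned over the
outpatient decision tree (see `docs/methods.md`).

## Worked example

The three packaged scenarios reproduce the published study set-up: 100
patients over three years, NYHA mix 0/61/37/2 %, mean of 10 runs,
with ambulance, medication, transport costs and extramural mortality
excluded.

```bash
hfcaresim fixtures --out scenarios
hfcaresim run scenarios/study_scenario_conventional.yaml --out results/conv
hfcaresim run scenarios/study_scenario_tm_a.yaml --out results/tm_a
hfcaresim compare results/conv results/tm_a
```

prints (seed 12345, as packaged):

```
total cost (mean of 10 runs): 554078.02 EUR; deaths: 13.3     # conventional
total cost (mean of 10 runs): 651316.81 EUR; deaths: 9.7      # telemedical A
year 1: ... 185550 EUR, ... 214918 EUR (115.8% of reference)
year 2: ... 180036 EUR, ... 226400 EUR (125.8% of reference)
year 3: ... 188492 EUR, ... 209999 EUR (111.4% of reference)
no break-even within the horizon
deaths: {'study_scenario_conventional': 13.3, 'study_scenario_tm_a': 9.7}
```

Reading: under variant-A financing (100 EUR per patient-month) the
telemonitoring arm prevents roughly a third of admissions and of deaths
(9.7 vs 13.3 over three years), but the system fees outweigh the inpatient
savings every year. Under variant B the picture inverts over time — yearly
costs fall from 137.6% of conventional care in year 1 to 79.5% in year 3
as the one-off acquisition cost amortises. How far these headline numbers
can be pushed toward the published scenario outcomes depends on branch
probabilities the study does not report; `docs/methods.md` lists which
inputs are published and which are documented assumptions.

Sensitivity sweeps vary one parameter at a time with everything else
(including seeds) fixed:

```bash
hfcaresim sweep scenarios/study_scenario_tm_a.yaml \
    --param financing.monthly_rate_per_patient_eur --values 40,70,100 \
    --outputs total_cost_eur,deaths
```

Everything the CLI does is also available as a library
(`hfcaresim.run_scenario`, `hfcaresim.compare_arms`, ...), and every report
number is recomputable from the serialised per-run event logs.

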
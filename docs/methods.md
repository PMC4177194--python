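# Methods

## Model structure

The simulator is a stochastic discrete-event model with a fixed one-day
time step over a half-open horizon `[0, H)` days. Each patient is an
independent agent with a NYHA class (1–4), a location (outpatient,
hospitalised, dead), and named random substreams. Two model variants exist
— conventional and telemedical care — that differ **only** in the
outpatient block; the inpatient block and its parameters are shared, and
any between-arm difference in admissions arises from the arm-specific
outpatient parameters, not from structural differences in hospital care.

### Outpatient block, conventional arm (daily cycle)

Per outpatient day: worsening with probability `w`; if worsening, an
emergency admission with probability `e`; otherwise one response drawn
from (medication change, GP, specialist, ambulance) with probabilities
summing to 1; improvement with probability `i` ends the cycle; on failure,
extramural death (only when that outcome is enabled) with probability `m`,
else referral admission with probability `r`, else the contact simply
carries over. The care pathway's unbounded "no improvement" loop is
resolved within a single day — one contact, one improvement check, then
death/referral/carry-over — which is the minimal reading consistent with
the one-day time step.

Routine (non-triggered) GP and specialist visits are a homogeneous Poisson
process at per-patient-year rates (year = 365.25 days), scheduled once per
run at the patient's initial severity class and suppressed while the
patient is hospitalised. They are modelled as independent of the
worsening-triggered contacts: the source data reports average contact
counts without decomposing them, so the packaged scenarios treat the
published rates as the routine baseline and triggered contacts as
additional.

### Outpatient block, telemedical arm (weekly control cycle)

Daily data transmissions are cost-free bookkeeping; system costs enter
only through the financing block. Clinical branching happens every 7th day
(days 6, 13, …; exactly `H // 7` cycles per horizon): alarm with
probability `a`; then emergency (probability `e`, shared with the
conventional pathway), or a remote intervention that succeeds with
probability `s`; on failure a contact drawn from (home visit, doctor
visit, hospitalisation); after a face-to-face contact an adaptation check
(probability `d`) ends the cycle, else extramural death / referral as in
the conventional arm. After an alarm cycle resolved outside the hospital
the patient's NYHA class is redrawn from the same (improve, stay, worsen)
triple used at discharge; cycles without an alarm leave the class
unchanged (the pathway description does not fix the frequency of this
step; tying it to alarms is the conservative choice, since alarm-free
weeks carry no clinical event to justify a transition).

### Inpatient block

An admission is resolved at arrival: ICU involvement (probability per
admission), ward and — when ICU care occurs — ICU lengths of stay, at most
one individual medical procedure (IMP) drawn from a weighted catalogue,
and survival. On survival the discharge NYHA class moves by at most one
grade, clamped to 1–4, and the patient re-enters outpatient circulation
the day after discharge. Resolving the stay up front is equivalent, for
costing and outcomes, to explicit day-by-day ward↔ICU transfers, which the
underlying data does not parameterise; the reimbursement needs only day
counts. ICU days are placed at the head of the stay (decompensation →
intensive care → step-down), so a death that truncates the stay cannot
erase ICU involvement. Death timing within a fatal stay is uniform over
the drawn stay — the minimal assumption; it affects only within-stay cost
censoring. Mortality, ICU and IMP draws are independent given the NYHA
class: severity enters only through class-specific parameters, with no
additional ICU–mortality coupling.

### Length-of-stay distribution

Only medians are published, so stays are log-normal parameterised by the
continuous median (`exp(μ) = median`) with log-scale dispersion σ
(default 0.5, a right skew typical of length-of-stay data), rounded up to
whole days with a floor of one day. `σ = 0` degenerates to a fixed
`ceil(median)`-day stay for exact tests. A boundary artefact worth knowing:
with the conventional-arm median at exactly 10 days, `P(stay ≤ 10) = 0.5`
exactly, so the empirical integer median of a large sample sits on the
10/11 knife edge and either value can appear; the telemedical median 6.5
rounds stably to 7.

### Hazard calibration

Published admission risks are per reference period (182 days, the
six-month follow-up of the source admission data; the period length is a
config field). A per-period probability `p` converts to a daily hazard
via `1 − (1 − h)^T = p`. Because admissions in the model arise from the
decision tree rather than from a bare hazard, the packaged scenarios
invert the tree: the per-day admission probability equals
`w·(e + (1−e)(1−i)(1−m)r)` in the conventional arm, so `w` is set to
`h` divided by that bracket (and analogously the per-cycle alarm
probability `a` in the telemedical arm, with `T/7` cycles per period).
The `hospitalization_counting` switch selects the alternative reading of
the published figure as expected admissions per patient-period
(`h = p/T`); the default reads it as the probability of at least one
admission.

## Costs

All amounts are held as integer euro cents; category subtotals therefore
add to the total exactly. Inpatient stays follow the case-flat-rate
scheme: flat score `F` for total stays (ward + ICU days) within the trim
points (4–12 days), `F + s·(L − 12)` beyond, reduced flat rate `f·F`
below; ICU days add a daily supplementary score; IMPs add catalogue
points; points × euro-per-point (default 1.0) give euros. The packaged
tariff interprets the published 1523 EUR in-hospital amount as the
within-trim flat score (not per day) and the 2496 EUR intensive-care
amount as the cost of a median two-day ICU stay, i.e. 1248 points per ICU
day — both overridable. The whole admission is booked on the admission
day (the record, including any death truncation, is resolved then); fatal
stays are priced by days actually accrued.

Telemonitoring financing: variant A books one flat rate per patient at
each completed month (month = 30.4375 days; a 3-year horizon of 1095 days
thus completes 35 months); variant B books a per-patient acquisition at
day 0, a cohort-level overhead per month for the **whole horizon** (the
overhead is a service contract, deliberately not per patient), and a
per-patient physician fee per month. Per-patient fees stop with death —
patients are charged only for whole months survived.

## Parameters

| Parameter | Unit | Conventional | Telemedical | Status |
|---|---|---|---|---|
| median ward stay | days | 10 | 6.5 | published |
| median ICU stay | days | 2 | 2 | published |
| hospitalisation / 182 d | % | 32.08 | 20.37 | published |
| GP visits | /patient-year | 1.42 | 2.84 | published |
| specialist visits | /patient-year | 0.3 | 0.46 | published |
| ICU involvement | % of admissions | 12.6 | 12.6 | published |
| in-hospital mortality | % of admissions | 7.1 | 7.1 | published |
| GP / specialist tariff | EUR | 25 / 31 | 25 / 31 | published |
| flat score, trim 4–12 d | points | 1523 | 1523 | published |
| ICU supplement | points/day | 1248 | 1248 | derived |
| emergency given worsening `e` | prob. | 0.30 | 0.30 | assumption |
| medication / GP / spec. / amb. split | prob. | .30/.40/.20/.10 | — | assumption |
| improvement after contact `i` | prob. | 0.80 | — | assumption |
| referral if no improvement `r` | prob. | 0.70 | 0.70 | assumption |
| extramural mortality `m` | prob./cycle | 0.02 | 0.02 | assumption (off) |
| discharge transition (↑, =, ↓) | prob. | .30/.55/.15 | .30/.55/.15 | assumption |
| IMP probability / points | per adm. | 0.10 / 5000 | 0.10 / 5000 | assumption |
| ward daily supplement `s` | points/day | 100 | 100 | assumption |
| reduced flat fraction `f` | — | 0.7 | 0.7 | assumption |
| intervention success `s_tm` | prob. | — | 0.60 | assumption |
| contact split (home/doctor/hosp.) | prob. | — | .40/.40/.20 | assumption |
| adaptation success `d` | prob. | — | 0.70 | assumption |
| worsening `w` / alarm `a` | per day / cycle | 0.005335 | 0.021642 | calibrated |

The published per-class inputs are cohort aggregates, so the packaged
scenarios apply them uniformly to all four NYHA classes; the schema fully
supports class-specific gradients for user scenarios. Assumption values
were fixed once, as clinically plausible magnitudes, before any scenario
comparison, and are marked as assumptions in the fixture files.

## Randomness and reproducibility

Every draw goes through a named substream: SHA-256 of a hierarchical label
(`arm/run-k/patient-i/{init,routine,outpatient,inpatient}`) spawns a
`numpy` SeedSequence key together with the scenario seed. Consequences:
identical (config, seed) runs are bit-identical; enlarging the cohort
leaves existing patients' trajectories untouched; runs and arms use
independent streams (no common random numbers across arms — users doing
paired comparisons should difference means, not runs).

## What the packaged scenarios can and cannot show

The scenario generator reproduces the published study conditions (cohort,
horizon, NYHA mix, tariffs, financing variants, excluded cost
components). With the documented assumptions the simulated three-year
comparison shows the qualitative published pattern — telemedical care is
more expensive in year 1 under both financing variants (≈116% and ≈138%
of conventional), the ordering is strongly financing-sensitive, variant B
falls below conventional care's yearly cost from year 2 (91%) and further
in year 3 (80%), and deaths drop (≈13 vs ≈10 per 100 patients). The
published point outcomes (savings of up to 8% over three years,
break-even near two years, 14 vs 7 deaths) additionally depend on branch
and transition probabilities that were never published; they are not
reproduction targets of this package, and the acceptance checks instead
pin down the published tariff arithmetic, the recovery of every published
event parameter, and the model's structural invariants.

Features of real care the generator does not emulate: medication and
travel/indirect costs, appointment queues and capacity constraints,
telemonitoring adherence and alarm error rates, class jumps of more than
one NYHA grade, and any coupling of ICU involvement with mortality beyond
severity class.

## Numerical choices and degenerate inputs

Money: integer cents, rounding once per booked line. Probability groups
must sum to 1 within 1e-9. Categorical draws guard the `u ≈ Σweights`
round-off edge by returning the last positive-weight index. `p = 1`
Bernoulli draws are certain despite `random() ∈ [0, 1)`. Hazard
conversion uses `expm1`/`log1p` for small-probability accuracy and is
exact at `p ∈ {0, 1}`. NYHA transitions clamp at the 1 and 4 boundaries
(improving at 1 and worsening at 4 mean "stay"). Degenerate scenarios
(all probabilities 0, zero tariffs, one-day horizons) are exercised in the
test suite and accrue exactly nothing.

## Problem sizes

The full packaged comparison (3 scenarios × 10 runs × 100 patients ×
1095 days) runs in a few seconds. The statistical verification layer uses
100 000 draws for admission-level quantities (3σ binomial bounds ≈ 0.3
percentage points) and 10 000 patient-years for visit rates; these sizes
put the Monte-Carlo error well inside the printed precision of the inputs
being recovered.
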
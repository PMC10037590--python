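# Methods

## The problem and the data model

Claims-based fracture studies ascertain outcomes from three administrative
sources: inpatient discharge abstracts (admission/discharge dates, ICD-10-CA
diagnoses with a position field where position 1 is the most responsible
diagnosis, and CCI procedures), emergency department records (diagnoses and,
where the data holding permits, procedures), and outpatient physician fee
claims (a single service code per claim; for radius/ulna fracture care the
OHIP fee code 813).  Hip fractures have no outpatient diagnosis code in
this environment, so hip definitions draw only on inpatient and emergency
sources.  All dates are calendar dates; every window in the package is
inclusive of both endpoints.

A cohort member contributes follow-up from an index date (cohort entry) to
the earlier of death and the administrative study end.  Person-time is
**not** censored at fracture: every definition shares one denominator, so
the ratio of two definitions' rates equals the ratio of their counts.
This mirrors how the published per-definition tables behave (a constant
implied denominator across rows) and keeps "% captured" and the rate
column mutually consistent.

## Hospitalization episodes

Claims of one hospitalization share an episode: inpatient claims are
grouped by their episode id (admission = earliest admission date,
discharge = latest discharge date), and an emergency claim is attached to
an episode when its service date falls within `ed_linkage_days` (default
1) before the admission date, inclusive on both sides — the typical
ED-visit-then-admission transfer pattern.  The default of 1 day is a
design choice; real data holdings differ in whether ED and inpatient
records of one stay are linked, so the window is configurable (0 treats
only same-day visits as the same stay).  An unattached ED visit forms a
singleton pseudo-episode spanning its own date, so "same hospitalization"
confirmation rules degrade gracefully for non-admitted patients.
Overlapping inpatient episodes with distinct ids are kept (with a
warning): claims data do contain interleaved stays (transfers), and
collapsing them would silently change episode-linked confirmations.

## Definitions and evaluation

A definition is declarative: diagnosis sources ⊆ {I, E, O};
`primary_dx_only`; an optional outpatient corroboration rule (a fee-claim
diagnosis counts only when a second outpatient diagnosis falls within 90
days before or after it; inpatient and emergency diagnoses bypass the
rule); a confirmation requirement (`none`, `procedure`, or
`procedure_or_death`) with its own source set and a linkage mode.
Linkage modes and their semantics, relative to a diagnosis on day *d*:

| mode | procedure qualifies when | death qualifies when |
|---|---|---|
| `within_days(k)` | procedure date in [*d*, *d*+k] | death in [*d*, *d*+k] |
| `same_episode` | procedure's claim shares the diagnosis claim's episode | death on/before the episode's discharge |
| `same_episode_or_within_days(k)` | either of the above | either of the above |
| `any_time` | procedure on/after *d* | death on/after *d* |

Day windows are forward-looking: confirmation follows diagnosis.  Death
"during the same hospitalization" is read as death on or before the
episode's discharge date (in-hospital deaths are recorded at discharge).
Death stands in for the patient too frail for surgery, which is why the
most inclusive confirmed definitions accept either.

The thirteen built-in hip definitions run from the referent (any
inpatient-or-emergency diagnosis) down to emergency-only diagnoses with
procedure confirmation; the seven radius/ulna definitions from any-source
diagnosis down to inpatient-only.  Two encoding choices were genuinely
open and are worth flagging:

* the emergency-only "diagnosis + procedure" definition without a stated
  window is encoded as `any_time` (procedure on or after the diagnosis):
  it demonstrably captures more events than its 7-day sibling, which
  rules out a narrower reading;
* the radius "diagnosis + procedure within 90 days" definition carries no
  source restriction and uses all three sources for both diagnosis and
  confirmation.

Evaluation identifies the **first** qualifying fracture per patient:
hits in chronological order, same-day ties broken inpatient → emergency →
outpatient and then by claim id (a pure determinism device; nothing in
the outputs depends on it except reproducibility), first hit passing the
outpatient rule and confirmation wins.  Event provenance flags record
subtrochanteric coding (S72.2 on the qualifying diagnosis), replacement
confirmation (1VA53 among the confirming procedures), and trauma
association.

A `secondary_cohort_mode` flag models a data holding whose emergency
records carry no procedures: E is removed from every confirmation source
set and definitions left without confirmation sources are dropped as
untestable.

## Sensitivity analyses

* **180-day washout** — an event is discarded when any same-site fracture
  claim (from any source valid for the site, including pre-index lookback
  claims) falls in [event − 180 d, event − 1 d].  Same-site scope matches
  the per-site analyses; the window endpoint is inclusive.
* **Trauma exclusion** — an event is discarded when a V/W external-cause
  code appears on a qualifying claim, on any claim of the event's
  hospitalization episode, or on any inpatient/emergency claim within ±7
  days of the event.  The ±7-day association window is a design choice
  (how a trauma code is "associated" with a fracture is not standardised);
  it bounds the acute encounter and is configurable.  Outpatient claims
  never carry external-cause information and never count.
* **Subtrochanteric exclusion** and **hip-replacement exclusion** —
  re-run the engine against a registry with the S72.2 (respectively
  1VA53) pattern removed.

Exclusion analyses **re-identify** the first fracture among the remaining
qualifying hits: a patient whose earliest event is washed out or
trauma-linked may contribute a later clean event.  The alternative —
dropping the patient — is equally defensible on the published evidence;
re-identification was chosen because retention is reported as a percent
of event counts, which implies counting whatever events survive.  Either
way a variant's per-definition count can never exceed the primary count,
and the suite asserts this.  The trauma code set is implemented as the
full ICD-10-CA V/W chapters (the canonical injury-indicator core list is
a narrower published subset; the registry accepts a substitute list).

## Report arithmetic

Years are 365.25 days.  Table cells use decimal half-up rounding at one
decimal (percent reductions in prose style at zero decimals), which is
what reproduces the published cells exactly.  Quartiles of time to
fracture use linear interpolation between order statistics (the common
default; configurable in principle via the quantile call).  Median time
is computed over patients with an event only.

The printed radius/ulna incidence cells for definitions 3–5 (8.5, 4.3,
3.7) are inconsistent with their printed counts under the shared
denominator (they should be ≈78.5, 74.3, 73.7 — dropped leading digits);
they are excluded from the reference values and from verification.

## The synthetic-claims generator

The generator emulates the *structure* of the study environment, not any
real cohort's numbers: patients aged 66+ (ages 66 + Poisson(8), median
74; 80% female) with index dates uniform over April 2003–December 2016,
followed to March 2020 or death (exponential, 0.03/year).  Hip and
radius/ulna fractures arise as first-event exponential processes
(defaults 0.012 and 0.010/year — rates in the neighbourhood of what
older osteoporosis-treated cohorts show, scaled for a clearly signal-rich
test bed).  Each true event expands into claims through a per-site coding
model whose probabilities are **independent across sources**; that
independence is what gives the diagnosis-only definitions closed-form
capture probabilities (e.g. capture(IE-dx) = 1 − (1 − p_ed)(1 − p_inp)),
which the suite recovers from engine output within 3 binomial standard
errors at 20,000 patients.

Default coding models encode the clinical contrast the analysis turns on:
hip events are almost always seen in the ED (p_ed = 0.85) and admitted
(p_inp = 0.92) with a procedure usually coded (0.88) and replacement a
substantial share of procedures (35% — so excluding the replacement code
visibly guts procedure-confirmed definitions); radius/ulna events are
mostly outpatient (p_out = 0.90, second corroborating claim 0.70) with
uncommon admission (0.25).  Hospitalized events get a length of stay from
a geometric distribution (mean 7 days; only episode containment matters),
an ED claim dated the admission day (deliberately exercising the
ED-episode linkage), procedures dated 0–2 days after admission, and a 90%
chance the fracture diagnosis sits at position 1.  Acute deaths
(probability 0.06 hip, 0.01 radius within 7 days) pull the death date
forward; trauma co-codes (2% hip, 5% radius) and subtrochanteric coding
(5% of hip events) drive the corresponding sensitivity analyses;
pre-index fracture history (5% per site, dated up to a year before index)
feeds the washout.  Background non-fracture claims (0.5/person-year,
drawn from ICD chapters disjoint from the fracture and trauma sets) add
realistic noise that must never produce an event.

What the generator does **not** model — and what passing tests therefore
do not show about real data: correlated coding across sources (real ED
and inpatient records of one event are not independent), miscoding into
or out of the fracture code sets, recurrent fractures beyond the single
pre-index event, code drift over calendar time, and any calibration to
real absolute counts (impossible without the source data and circular if
attempted).  The parameter-recovery and nesting results validate the
machinery, not the epidemiology.

## Problem sizes and determinism

Everything is driven by one seeded `numpy` generator per simulation
config; identical configs give byte-identical tables, and the engine is
deterministic given its inputs.  The shipped analyses use 10,000 patients
(analysis scripts) and 20,000 patients (capture-probability recovery in
the acceptance script and suite); oracle-equivalence checks run on
≤100-patient instances against a brute-force (hit × confirmation)
enumeration kept in the test suite.  These sizes give every definition a
non-degenerate event count and binomial standard errors small enough for
the 3-SE recovery bound to be meaningful.
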
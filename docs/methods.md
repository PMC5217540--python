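# Methods

## Problem

Smoking status in UK primary care is recorded opportunistically with Read
V2 codes.  A single record can contain, over a lifetime, never-smoker
codes, ex-smoker codes, current-smoker and intensity codes, cessation
therapy prescriptions (NRT, bupropion, varenicline), cessation
administration/advice codes, and the bare hierarchy parent code `137..`
with or without a cigarettes-per-day value.  Naively taking the latest
status code misreads relapse, ignores therapy evidence, and accepts
"never smoked" entries made after a documented smoking history.  The
classifier here resolves these conflicts at any census date using the
whole life course.

## Classification model

The per-patient state is six dates: first/last recorded date of a code in
each base category (NEVER, EX, SMOKER).  A code contributes to a category
via the codelist; the parent code contributes SMOKER evidence only with a
value > 0 (a zero may mean non-smoker or smoker depending on the
recording GP, so it is uninformative, as are unknown codes).  Evaluation
order at census *t*:

1. empty summary → NO_INFORMATION;
2. nothing on/before *t* → LIKELY_SMOKER if the record is purely
   smoker-category, else UNKNOWN_SMOKING_STATUS;
3. spans containing *t*: smoker + (ex or never) → RELAPSED_SMOKER;
   smoker → SMOKER; ex → EX_SMOKER; never → EX_SMOKER if any ex/smoker
   evidence starts on/before *t* (temporal checking), else NEVER_SMOKER;
4. no span contains *t*: category of the nearest first/last boundary
   date, with the same never→ex override.

Design choices made where the published description left room:

* **"Prior to" is read as on-or-before**: a code recorded on the census
  day reflects status on that day.  The predicate is isolated in one
  helper so the strict reading is a one-line change.
* **Rule order** (relapse before smoker before ex before never) is the
  only order consistent with all seven narrative census scenarios.
* **Nearest-date search uses the six boundary dates**, not all events —
  the gap scenarios are narrated purely in terms of first/last dates.
* **Ties** (equidistant or same-day boundaries): prefer the date
  on/before the census, then SMOKER > EX > NEVER — conservative toward
  smoking, consistent with treating therapy evidence as smoking.  In
  simulated cohorts ties occur in well under 1% of classifications, so
  this choice cannot move agreement statistics materially.
* **LIKELY_SMOKER takes precedence over UNKNOWN** when both match; the
  class exists precisely for the all-smoker-codes-after-census record.
* The **no-temporal variant disables only the never→ex override**;
  relapse detection is retained (the published no-temporal table has a
  *larger* smoker row than the full algorithm's, which rules out relapse
  having been disabled as well).

The nearest-status variant consumes status/intensity/parent codes only
(therapy, administration and advice codes are excluded before reduction)
and returns the collapsed four-level scale directly.

`classify_full`/`classify_no_temporal` take `(summary, census)`: every
rule above is a function of the six dates, so the classifiers do not need
the raw event list.

## Codelist

The packaged codelist (`data/codelist_synthetic_default.csv`) is a
synthetic representative stand-in: the original research codelist is not
publicly distributable, so this file mirrors the published group /
sub-group structure (all 21 sub-groups, with large groups such as the 91
NRT product codes collapsed to a few representative entries) using
plausible Read-V2-style code strings.  Every operation takes the registry
as an argument, so a real codelist drops in via `load_codelist`.

Intensity bands overlap as published ("less than 20 and greater than 0"
for medium contains the light band); they are resolved as half-open
escalating bands: [1,10) light, [10,20) medium, [20,40) heavy, ≥40 very
heavy; time-to-first-cigarette >60/≤60/≤30/≤5 minutes respectively; the
heavier class wins when both measures are present.  "Trivial smoker" has
no numeric band and is assignable only via explicit codes.

## Agreement analysis

Survey items 1–5 map to smoker (1–2), ex-smoker (3–4), never smoker (5).
GP collapsed status × survey status forms a 4×4 table with missing
first row/column.  Kappa is computed on complete pairs only — verified
numerically as the only choice reproducing all six published kappas —
with the large-sample standard error √(P₀(1−P₀)/(N(1−Pₑ)²)) and 95% CI
κ ± 1.96·se, which reproduces every published interval to 2 dp.
Discordance denominators are full survey column totals including
GP-missing rows (again the only reading matching the published
percentages).  Percentages are reported at the published precision.
An optional output mode renders cells below 5 as "<5" while keeping
totals true, mirroring disclosure control in trusted research
environments.

Two published inconsistencies are preserved rather than patched over:
the prose reports 8.6% and 4.3% where the corresponding tables give 8.5%
and 4.4% — this package reports table-derived values — and the
nearest-status table's printed missing-row total (423) disagrees with its
own cells (432); the packaged encoding is cell-consistent and flags the
erratum (`reference.NEAREST_ROW_TOTAL_ERRATUM`).

## Prevalence

Annual prevalence classifies everyone aged ≥16 at a mid-year census
(July 1, configurable — the original does not state its within-year
reference point) with the full algorithm, collapses, and divides smokers
by the non-missing classified count.  Whether the original denominator
was the registered population or the classifiable one is unstated, so
both modes exist (`include_missing`).

## Synthetic cohort generator

Emulates the linked-study design: a yearly two-state (smoking/quit)
Markov chain after a Bernoulli initiation, sporadic GP observation, and a
one-off survey self-report.

Defaults (one cohort = one set of study conditions, chosen once as a
plausible UK adult population and not tuned): 2000 patients aged 16–84 at
a 2013 survey; lifetime initiation probability 0.5 at age 14–25; annual
quit probability 0.04 and relapse probability 0.02; GP visits Poisson
with mean 3/year from age 16 within a 2000–2015 recording window; a
visit leaves a smoking code with probability 0.2, always consistent with
the current true state; a smoker's code is a therapy/administration/advice
code with probability 0.15, otherwise a status/intensity code or (20% of
the time) the parent code with a positive cigarettes-per-day value;
at survey, a true ex-smoker self-reports "never" with probability 0.25
(smoker under-reporting exists as a parameter, default 0).  Randomness
uses one root seed with a per-patient `SeedSequence` substream, so output
is byte-stable and per-patient regeneration does not depend on cohort
size.

What it deliberately does *not* emulate: within-year quit/relapse timing
(truth changes at year boundaries), miscoding (recorded codes never
contradict the current true state), demographic or practice structure,
registration gaps, e-cigarette coding.  Consequently the recovery tests
show that the *classifier* faithfully inverts the *observation process
modelled here*; they do not certify accuracy on real records, where
coding itself is unreliable.

Under dense faithful recording (visit rate 12/year, recording probability
1, no misreporting) the pipeline recovers the generator's truth at the
survey date for ≥99% of 2000 patients.  The residual disagreements are
structural, not bugs: a patient who relapses *after* the survey acquires
a smoker span overlapping the census (RELAPSED, collapsed to smoker,
versus true ex at the survey), and a patient who turned 16 shortly before
the survey may have no code yet (UNKNOWN).  Raising the ex→never
misreporting probability inflates the (GP-ex, survey-never) cell — the
mechanism behind the large published never→ex discordance — and raising
the therapy-code share makes the full algorithm find more smokers than
the nearest-status variant, since the latter discards therapy evidence.

## Numerical and interface conventions

Day is the temporal resolution; same-day conflicting codes are all
retained and surface through the relapse rule.  All CSVs are UTF-8 with
headers and ISO-8601 dates.  Output ordering is deterministic
(lexicographic patient id).  CLI exit codes: 0 success, 1 validation
error, 2 I/O error.  Problem sizes in the test suite (10,000 randomized
summaries for the totality/monotonicity sweep; 2000-patient recovery
cohorts; 600–800-patient cohorts for the qualitative phenomena) keep the
full suite around ten seconds while leaving Monte-Carlo margins wide
relative to the thresholds tested.

## Known limitations

* The packaged codelist is illustrative; real deployments must supply
  the codelist used by their database.
* The reconstruction of the classification flow follows the published
  class definitions and scenario narrative; the original SQL itself was
  published only as a figure, so any divergence from it cannot be
  detected from the text.
* Kappa CIs are large-sample; no bootstrap or weighted kappa.
* No imputation of missing status; no age-specific re-asking rules
  (those govern data collection, not classification).
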
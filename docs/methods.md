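# Methods

## Disproportionality model

The analysis unit is the deduplicated spontaneous report. For a drug of
interest *D* and an event *E* (a single MedDRA preferred term, default
"Headache"), reports are cross-classified as

|            | event E | other events |
|------------|---------|--------------|
| PS drug D  | a       | b            |
| other drugs| c       | d            |

where "PS drug" means the drug with role code PS (Primary Suspect) on the
report. Each report carries exactly one PS unit, so the *a* cells across
drugs partition the event reports, and `a+b+c+d` equals the background
size. Secondary-suspect, interacting and concomitant mentions are
excluded everywhere — including the comparator cells — to keep the
comparison between primary-suspect exposures only.

Two frequentist disproportionality measures are computed per drug and per
ATC level-2 class:

* **ROR** (reporting odds ratio) `= ad/bc`, with Wald interval on the log
  scale using `SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)`;
* **PRR** (proportional reporting ratio) `= [a/(a+b)] / [c/(c+d)]` with
  `SE(ln PRR) = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))`.

Both intervals use the conventional quantile 1.96 (not the exact 97.5%
normal quantile; the difference is below 2·10⁻³ %). A **signal** requires
all four conditions: both point estimates above 1 and both lower 95%
bounds above 1. In the rare-event regime typical of this data
(`a/b ≪ 1`, background event share a few percent) PRR converges to ROR;
the test suite checks this limit explicitly.

Assumptions worth stating: reports are treated as independent; no
adjustment is made for multiple testing (the manifest records this
caveat), indication bias, or reporting dynamics. These are inherent
limits of disproportionality screening, not implementation choices.

### Degenerate tables

A zero in any cell makes the ROR or its variance undefined. No
Haldane–Anscombe 0.5 correction is applied: the estimate is returned as
*undefined* with a zero-cell flag, and an undefined estimate can never be
a signal. A silent correction would re-rank drugs without leaving a
trace, which is worse than an honest gap. The PRR remains defined for
`b = 0` or `d = 0` (its variance term cancels) but not `a = 0` or `c = 0`.

## Deduplication

FAERS re-issues a case each time it is amended; versions share a CASEID.
Within a CASEID the kept version maximises `(FDA_DT, PRIMARYID)`:
latest receipt date first, highest report-version id on ties. Missing or
unparseable FDA_DT sorts before any real date, so a dated version always
beats an undated one (the count of such groups is logged). PRIMARYIDs
are compared numerically when all ids are digit strings — the FAERS
convention — with a logged lexicographic fallback otherwise. The
operation is idempotent and invariant to input order, and runs on the
concatenation of all quarters before any filtering.

## Time-to-onset

Onset is the calendar-day difference between the report's event date and
the PS drug's therapy start date. The DRUG row's START_DT is preferred;
when it is not an 8-digit valid date the THER row matching that drug
sequence is used instead (FAERS stores start dates in both tables and
neither is authoritative; the preference order is fixed and logged).
Only complete day-resolution pairs qualify; month/year tokens and
negative differences are excluded under separate counters
(`incomplete_start`, `incomplete_event`, `negative`), so
`complete + excluded = candidate units` always holds. Day 0 (same-day
onset) is counted in the first bin rather than dropped — infusion-type
reactions are real data, and there is no principled lower cut.

Bins are `≤7`, `8–28`, `29–60`, `61–90`, `>90` days — a partition of the
non-negative integers, checked exhaustively in the tests. Per-group
percentages are computed independently per bin from its own count and
rounded half-up to one decimal; they are not renormalised to force a
100.0 sum, so the printed columns always recompute exactly from the
printed counts.

## Demographic summary

Ages are normalised to years from FAERS unit codes (YR, DEC, MON, WK,
DY, HR) before banding; an unrecognised code yields Missing rather than
a guess. Age bands are `<18, 18–30, 31–50, 51–65, >65` with integer-age
semantics: 18 belongs to 18–30 and 65 to 51–65 (the outer bands are
strict). Weight uses `≤50`, `>50–≤100`, `>100` kg with LBS converted at
0.4536 kg/lb. Coded-unknown sex is a category distinct from blank
(Missing). Countries outside the individually reported set (United
States, Canada, United Kingdom, Denmark, Country Not Specified) pool
into "Others". Every characteristic's categories, including Missing,
sum to the cohort size, and every percentage column recomputes from its
count column under half-up rounding to two decimals.

## Synthetic study design

The generator emulates the statistical structure the pipeline must
survive, not the content of any real extract:

* **Planted associations.** Each case draws one PS drug from the
  configured panel by marginal share; unclaimed share is absorbed by
  filler drugs with odds ratio 1 so every case has a primary suspect.
  The event is Bernoulli with odds `(p₀/(1−p₀))·R`, where `p₀` is the
  background event rate and `R` the drug's planted ROR. Planting on the
  odds scale (rather than a rate ratio) makes the ROR estimator
  consistent for `R`, so coverage experiments have an exact target.
* **Duplicates.** A configurable fraction of cases (default 0.25, of
  which 10% get a third version) is emitted as multiple versions with
  earlier or tied receipt dates; for half of them the version ids are
  swapped so the latest-dated version does not always hold the highest
  id. Both tie-break rules are therefore load-bearing. With these
  defaults about 21.5% of raw rows are duplicate versions.
* **Dates.** Start and event tokens truncate independently to `YYYYMM`
  (70%) or `YYYY` (30%) at the configured rate (default 0.30 per
  token); therapy-table dates truncate independently of drug-table
  dates, so the start-date fallback path is exercised. 2% of cases get
  an event date before therapy start, exercising the negative-onset
  exclusion. Onset days are drawn per drug from a five-bin mixture
  (defaults shaped like an immunosuppressant profile: 45/13/8/4/30%),
  uniformly within the bin, with the open bin capped at 365 days.
* **Demographics.** Categorical distributions patterned on large-scale
  US-dominated spontaneous-report data: missing age/sex/weight at
  36.6/10.1/73.3%, consumers the largest reporter group, two-thirds of
  reports from the United States. Background event rate defaults to
  3.3%.
* **Truth table.** Each case's kept version id, PS drug, event flag and
  onset are recorded in a hidden table computed by direct maximisation,
  independent of the dedup module, and written as `truth.tsv` beside
  the bundle. Tests compare pipeline output against it; the pipeline
  never reads it.

What the generator does *not* emulate: indication records and their
biases, outcome severity, report versions whose content changes between
versions, MedDRA coding noise beyond literal PT strings, or drug-name
misspellings (name normalisation is tested on constructed inputs
instead). Passing tests therefore demonstrate correctness of the
pipeline's logic under known structure, not robustness to every artefact
of real-world coding.

## Problem sizes and numerical conventions

* The study-default configuration is 50,000 cases, 20 named drugs with
  three planted signals (ROR 4.0 / 3.0 / 2.0); unit tests run reduced
  panels of 800–12,000 cases.
* The coverage experiment uses 300 replicates of 20,000 cases with a
  planted ROR of 2.0 at 20% exposure; the 95% Wald interval is required
  to cover the truth in 93–97% of replicates (nominal 95%).
* Estimator oracle checks compare against independent formula
  evaluation on 10,000 random tables (relative tolerance 10⁻¹²) and
  against a generic 2×2 odds-ratio routine (statsmodels) on a sample.
* All reported rounding is half-up (`decimal`-based): estimates and CI
  bounds to 3 decimals, demographic percentages to 2, onset percentages
  to 1. Internal computation is double precision throughout; rounding
  happens only at the reporting boundary.
* Determinism: every random draw flows from a single
  `numpy.random.default_rng(seed)`; a fixed config reproduces bundles
  and pipeline outputs byte for byte.

## Known limitations

* Disproportionality measures quantify reporting imbalance, not risk;
  no causal or incidence interpretation is supported.
* ATC aggregation pools reports by class membership supplied as data;
  a drug mapped to several classes contributes to each, making class
  tables overlap (warned, not prevented). Unmapped drugs stay in the
  complement margins only.
* The report — not the drug–event pair — is the counting unit, so a
  report listing the event plus several reactions counts once.
* Version content is identical across synthetic duplicate versions, so
  dedup correctness is only tested on the keys that drive the rules
  (CASEID, FDA_DT, PRIMARYID), which is what the rules consult.
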
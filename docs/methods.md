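# Methods

## Data model

The toolkit operates on primary-care extracts shaped like CPRD Aurum raw
data: tab-delimited `.txt` files named
`<prefix>_setX_extract_<filetype>_0Y.txt`. `setX` (X ≥ 1) partitions
patients into batches; a patient's medical-event files carry the same set
token as their patient file. `0Y` numbers the parts of a file type within a
batch; both two- and three-digit padding occur in the wild, so the parser
accepts any digit width while the writer defaults to three. The prefix
varies between deliveries and is never interpreted.

File types and the columns the toolkit consumes:

| filetype     | key columns                                               |
|--------------|-----------------------------------------------------------|
| patient      | `patid`, `pracid`, `gender`, `yob`, `regstartdate`, `regenddate`, `cprd_ddate` |
| observation  | `patid`, `medcodeid`, `obsdate`, `value`, `numunitid`     |
| drugissue    | `patid`, `prodcodeid`, `issuedate`                        |
| hes_primary  | `patid`, `ICD10`, `admidate` (linked hospital primary diagnoses) |
| death        | `patid`, `dod` (linked death registration)                |

Unknown columns pass through verbatim. All identifiers are held as text:
Aurum `medcodeid`/`prodcodeid` values exceed 2⁵³, so numeric storage would
silently corrupt them. Dates are accepted as `dd/mm/yyyy` (the source
system's convention, and the tie-break for ambiguous strings) or ISO-8601;
unparseable date cells become missing with a logged count rather than
failing the read, since isolated malformed cells are routine in EHR
extracts. Files are streamed in chunks (default 10⁶ rows) so extracts
larger than memory can be ingested.

## Pipeline

**Cohort.** `extract_cohort` concatenates every file whose name contains
"patient", optionally subsetting to a known ID list and/or adding a `set`
column parsed from each source filename. Duplicate patids across patient
files are an error rather than being silently deduplicated — in a
well-formed extract the patient files partition the population, so a
duplicate signals a corrupted delivery. Output is sorted by numeric-aware
patid so results do not depend on directory order.
`assign_index_dates` supports a fixed date, a per-patient column, or their
elementwise maximum (e.g. the later of 1 Jan 2010 and the date a patient
turned 50). Inclusion/exclusion criteria are ordinary DataFrame filtering
and deliberately out of scope.

**Store.** Medical-event files are bulk-loaded into a single-file SQLite
database: one table per file type (overridable), no constraints and no
indexes by default so appends stay cheap and load cost is linear
(`build_index` can add a `(patid, code)` index afterwards for repeated
querying). Dates are stored as ISO-8601 text, which sorts
lexicographically in chronological order. Files are ingested in
deterministic (set, part, name) order — the first with overwrite, the rest
appended — making re-ingest idempotent. With a plain patid subset, every
row is membership-tested against the full set; with (patid, set) pairs, a
file parsing to set X is tested only against the patids of set X, which is
equivalent (the generator and real extracts guarantee events only reference
same-set patients) but much cheaper for multi-million-patient cohorts.
`rm_duplicates` removes exact-duplicate rows (equality on all stored
columns) across the whole extract after loading, not per file: duplicated
deliveries typically straddle file boundaries.

**Queries and windows.** `db_query` selects rows whose code column
(`medcodeid`, `prodcodeid` or `ICD10`, per the codelist's kind) is in the
codelist, joining any codelist annotation columns onto the output by code.
All index-date-relative logic is concentrated in one convention, used
identically by every extractor and by the raw-file oracle:

* event window `[t₀ + t − time_prev, t₀ + t + time_post]`, both endpoints
  inclusive (t = longitudinal offset in days);
* "history" means event date **≤** t₀ + t — a record on the index date
  counts as history;
* time-to-event search starts **strictly after** t₀ + t, so survival times
  are always positive.

The half-open treatment of the index day (≤ for history, > for
time-to-event) keeps history maximal while avoiding zero survival times;
both choices are flags on `Settings` for studies that define the boundary
differently. "Most recent" ties on the same day are broken by higher value
for test queries and stable input order otherwise, so output is
deterministic.

**Variables.** `extract_ho` and `extract_time_until` are thin compositions
of `db_query` with the window rules; `extract_time_until` returns
`(<var>_time, <var>_indicator)` with time capped at the censoring date and
the indicator 1 only when the first post-index event precedes censoring.
`extract_test_data` returns up to `numobs` most-recent in-window values per
patient after dropping missing values (configurable) and values outside
`[lower_bound, upper_bound]`; patients with no valid value contribute no
rows. `extract_test_data_var` returns the sample standard deviation
(divisor n − 1) of all valid in-window values, missing when n < 2, one row
per cohort patient.

Bespoke phenotypes:

* **BMI / cholesterol-HDL ratio** — two candidates per patient: the most
  recent directly recorded value, and a value computed from the most
  recent in-window components (weight/height²; total/HDL). The computed
  candidate's governing date is the later of its two component dates; the
  candidate with the more recent governing date wins, ties favouring the
  direct record (it needs no derivation). HDL = 0 invalidates the computed
  ratio. The exact candidate-recency rule beyond "components must lie in
  the window" is this package's design choice.
* **Height units** — records whose `numunitid` maps in a configurable
  code→factor table are scaled (default: centimetre codes × 0.01); unmapped
  heights above 3 (the tallest credible human in metres) are assumed
  centimetres. Real unit lookups are licence-gated, hence the configurable
  table plus heuristic. Non-positive converted heights are skipped with a
  logged count.
* **Diabetes** — any pre-index type-1 code ⇒ `type1`, else any pre-index
  type-2 code ⇒ `type2`, else `Absent`. Generic "diabetes mellitus" codes
  belong in the type-2 list: the precedence rule then reads them as type 2
  unless a specific type-1 code coexists.
* **Smoking** — status is the category of the most recent pre-index record
  across five per-category codelists; a most-recent non-smoker with any
  earlier smoking-category record is reclassified `Ex-smoker`; no records ⇒
  missing. Same-day ties resolve toward the heavier category so a same-day
  non-smoker record never masks a smoking record. A code in two categories
  is an error.

## Synthetic data

The generator emulates the extract's *shape*, not its clinical content:
numeric values are uniform integers 1–100, dates uniform between 1900-01-01
and 2000-01-01, gender ∈ {1, 2}, year of birth uniform 1900–2000, and
patient/practice IDs sequential. The worked-example fixture holds 12
patients split across two patient files (1–8 in set 1, 9–12 in set 2) with
three observation and three drug-issue parts, all in set 1; five
observations and three prescriptions per patient give each part a handful
of rows while keeping the tree readable.

`generate_study` adds ground truth: each code in `code_prevalences` is
planted per patient with the stated probability, dated strictly before the
recipe's index date; all other observations draw from a disjoint background
code pool, so a patient's truth flag equals "has any record of the code"
under either boundary convention. Truth flags go to a `truth.csv` sidecar.
Defaults — 2 sets, 2 observation files and 1 drug-issue file per set,
Poisson-distributed totals around 50 observations and 10 prescriptions per
patient, index date 2010-01-01 — give file trees big enough to exercise
chunking and the set fast path while generating in seconds. A fixed seed
yields byte-identical trees.

Because content is uniform noise, passing tests demonstrate *mechanical*
correctness (filtering, windowing, merging, unit conversion, determinism),
not robustness to real-data pathologies such as skewed code frequencies,
clustered recording, or systematically missing values.

## Verification strategy

The store-backed path is checked three ways on generated studies:
against `brute_force_history` — a deliberately independent for-loop over
the raw text files that re-reads, re-parses and re-filters them without
touching the store; against the generator's planted truth; and, for
windowed test extraction, against a pure-python per-row filter coded
separately from the pandas implementation. Problem sizes in the acceptance
script (2000 patients × ≈50 observations for the oracle check, 5000 for
prevalence recovery, 1000 for windowed extraction, 400 over 2 sets for the
fast path) are large enough that any boundary error flips at least one
patient, while the whole script runs in seconds. Prevalence recovery is
judged against the 99% binomial confidence interval of the planted rate.

## Known limitations

* Phenotype definitions are starting points, not clinical validations; the
  right definition varies by study and the functions are parameterised
  accordingly.
* Variable extraction from linked tables (`hes_primary`, `death`) is not
  provided beyond ingest and `db_query` with an `ICD10` codelist; linked
  files are small enough to handle in memory with user code.
* No concurrent writers; the store is a single-user analysis artifact.
* `referral`/`problem`/`consultation` files are read generically
  (configurable date columns) since their full schemas are not fixed here.
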
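# aurumkit

Turn raw CPRD-Aurum-shaped primary-care extracts into analysis-ready,
per-patient datasets.

## The problem

UK primary-care databases such as CPRD Aurum deliver their extracts as
thousands of tab-delimited `.txt` files — patient registration files plus
medical-event files (observations, prescriptions, referrals, …) named
`<prefix>_setX_extract_<filetype>_0Y.txt`, where `setX` partitions patients
into batches and `0Y` numbers the parts within a batch. At terabyte scale
this raw form cannot be read into memory, and ad-hoc loops over the files
are slow and error-prone.

`aurumkit` follows a four-stage process:

1. **Cohort** — concatenate the patient files and select the study
   population (`extract_cohort`, `assign_index_dates`).
2. **Store** — bulk-load the medical-event files for those patients into a
   single-file SQLite database on disk (`cprd_extract`, `add_to_database`),
   optionally exploiting the `setX` batching so each file is filtered only
   against the patients of its own batch.
3. **Variables** — query the store with *codelists* (curated sets of
   `medcodeid`/`prodcodeid` codes denoting one clinical concept) and derive
   per-patient variables relative to each patient's *index date* t₀:
   - history-of flag: 1{∃ record with code ∈ C, date ≤ t₀}
     (`extract_ho`);
   - time-to-event: (min{d − t₀ : d > t₀} ∧ censoring, event indicator)
     (`extract_time_until`);
   - most recent valid test value(s) in a window
     [t₀ − time_prev, t₀ + time_post] with value bounds
     (`extract_test_data`), and their sample standard deviation
     (`extract_test_data_var`);
   - bespoke phenotypes: BMI (direct or weight/height², with cm→m unit
     conversion), total-cholesterol/HDL ratio, diabetes status (type-1
     codes trump type-2/generic codes), and smoking status (a recent
     non-smoker with smoking history is reclassified ex-smoker).
4. **Dataset** — merge the extracted variables into one row per patient.

Every extractor accepts a day offset `t` so the same variable can be
re-extracted at fixed intervals for longitudinal analyses. The generic
primitives (`db_query`, `combine_query`, `combine_query_boolean`) are
exposed so users can define their own variables.

Because real extracts are licence-restricted, a synthetic-data module
generates extract-shaped file trees — including a 12-patient worked-example
fixture and study-scale trees where codes are planted pre-index with known
probability — so the whole pipeline is testable, and every extraction path
can be checked against a brute-force loop over the raw files
(`brute_force_history`) and against the generator's planted truth.

## Worked example

```python
import pandas as pd
from aurumkit import (StudyRecipe, generate_study, extract_cohort,
                      assign_index_dates, connect, cprd_extract, list_tables,
                      extract_ho, extract_test_data)

# 500 synthetic patients; code H1 planted before 2010-01-01 at prevalence 0.10
recipe = StudyRecipe(n_patients=500, code_prevalences={"H1": 0.10}, seed=42)
generate_study(recipe, "raw/")

cohort = assign_index_dates(extract_cohort("raw/"), fixed_date="2010-01-01")
print(f"cohort: {len(cohort)} patients")

store = connect("mydb.sqlite")
n = cprd_extract(store, "raw/", "observation", subset_patids=set(cohort["patid"]))
print(f"ingested {n} observation rows; tables: {list_tables(store)}")

ho = extract_ho(cohort, codelist_vector=["H1"], store=store, varname="ho_htn")
print(f"history of hypertension: {ho['ho_htn'].mean():.1%} of the cohort")

tests = extract_test_data(cohort, codelist_vector=["900000000001"], store=store,
                          time_prev=40000, lower_bound=20, upper_bound=80,
                          with_metadata=True, varname="sbp")
print(tests.head(3).to_string(index=False))
store.close()
```

prints

```
cohort: 500 patients
ingested 25130 observation rows; tables: ['observation']
history of hypertension: 9.0% of the cohort
patid    obsdate    medcodeid  sbp numunitid
  101 1999-10-27 900000000001   44        14
  238 1999-07-13 900000000001   54        71
  498 1999-04-30 900000000001   64        78
```

The 9.0% recovered history-of rate is the empirical realisation of the
planted 10% prevalence (Binomial(500, 0.10) noise); the test rows are each
patient's most recent in-bounds value with its date, code and unit.

A `aurumkit` command-line tool wraps the same stages
(`simulate`, `init-workspace`, `cohort`, `ingest`, `query`,
`extract <ho|time-until|test|test-var|bmi|cholhdl|diabetes|smoking>`); see
`aurumkit --help`.

### Workspace convention

`create_directory_system(root)` builds a standard tree — `data/sql/` for
stores, `codelists/analysis/` for codelist CSVs, `data/extraction/` for
extracted variables — after which stores and codelists can be referred to
by bare name (`extract_ho(cohort, codelist="mylist", db_name="mydb", ...)`)
and outputs are saved as `data/extraction/var_<name>[_t<offset>].csv`.

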
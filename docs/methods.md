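# Methods

## Setting and data model

The pipeline operates on de-identified administrative claims. Dates are
"derived dates": integer day counts since the patient's birth (day 0 =
birth), so age arithmetic is exact and no calendar handling is needed.
"≤28 days" and "≤18 years" are evaluated as `index_day <= 28` and
`index_day <= 18*365`. A dataset is three tables — patients, enrollment
spans (inclusive, non-overlapping), and claims (diagnosis codes in listed
order, procedure codes, revenue codes, an allowed amount, and an
inpatient/outpatient/pharmacy setting). The observation period of a patient
is the union of their enrollment spans: events outside eligibility are not
treated as observable.

## Code classification

All classification is table-driven by a catalog file (schema in
`code_catalog.py`). Matching is exact on normalized strings (uppercase,
periods stripped); range or prefix expansion is expected to be done upstream
when the catalog file is built. Diagnosis codes carry an age window because
several presentations suggest a genetic disorder only at particular ages
(isolated scoliosis in a newborn vs an adolescent); a code outside its window
simply does not classify. Codes for conditions with established targeted
diagnostics ("easy to diagnose") never qualify for cohort entry but still
count as transition destinations. Claims store bare code strings without an
ICD version flag; the catalog resolves them ICD-10 first, then ICD-9. The
repository ships a 40-code fixture catalog spanning every tier, flag and
category; it is a demonstration catalog, not a clinical code list.

## Cohort construction

Each cohort has its own index event: the earliest qualifying code, with
same-day ties broken by the diagnosis hierarchy definite > probable >
possible, then procedure categories, then the lexicographically smallest
code (a deterministic, auditable rule; real claims give no ordering within a
day). Continuous enrollment requires one merged span covering
`[index − min(180, index), index]`; adjacent spans (end day n, start day
n+1) leave no uncovered day and therefore merge. A configurable gap bridge
(default 0 — the strictest reading) can tolerate short administrative gaps.

Conservative and MCA/ID/DD/E membership is intersected with Broad
membership. With per-cohort index dates and imperfect enrollment the raw
criteria alone cannot guarantee the subset structure of the study design
(both cohorts are defined as refinements of Broad), so the intersection is
enforced explicitly.

The population split uses the Broad (primary) index date: critically-ill
newborns are cases indexed at ≤28 days of age with ≥1 NICU revenue-coded
claim inside the observation period at any time; all other cases up to 18
years at index are pediatric; patients older than 18 years at index are
excluded. Controls are patients with no qualifying code of any kind at any
time; their index date is the start of their first enrollment span. Patients
with codes that never qualify (e.g. only easy-to-diagnose or out-of-window
codes) are controls under this definition.

## Matching

Coarsened exact matching with k-to-k pruning. Categorical covariates are
exact; age at index uses bins {0–1, 1–5, 5–12, 12–19} years (half-open,
configurable) and birth year stays exact. Within a stratum the selection of
which min(n_cases, n_controls) units to pair is seeded-uniform rather than
nearest-neighbour: strata are already exact on the coarsened covariates, so
any within-stratum choice is balance-equivalent, and randomization avoids
input-order artifacts. Post-match L1 over matched units is exactly 0 by
construction (equal per-stratum counts on both sides); the L1 computation
clamps float-summation spill into [0, 1]. Propensity-score matching is out
of scope.

## Outcomes

* **Genetic tests** are counted as distinct (service day, code) pairs on or
  after the index date; repeat billing of one code on one day counts once.
  Days-to-first-test and test counts are summarized among tested patients.
* **NICU length of stay** counts distinct billed NICU days within
  enrollment; runs are split where the gap between billed days exceeds 1 day
  (room-and-board codes are daily; threshold configurable) and a patient's
  LOS is their total across runs, summarized among patients with ≥1 stay.
* **Diagnostic transitions** use the first-listed diagnosis on a claim as
  the primary diagnosis (the standard claims convention). A patient counts
  toward X→Y iff their index category is X and some strictly post-index
  primary code classifies as a more specific tier Y; denominators are the
  full cohort, so the combined possible-or-probable→definite fraction is
  exactly the sum of the two component fractions.
* **Cost accrual** bins allowed amounts into 30-day windows from the index
  date. A patient enters bin k's denominator only when one enrollment span
  covers the entire bin — full-bin enrollment avoids partial-exposure bias
  (pro-rating would be the alternative; the strict rule is simpler to audit).
  Pharmacy claims contribute to total costs only; inpatient and outpatient
  series come from the claim setting.
* **Demographic comparisons** use Welch's unequal-variance two-sided t test
  (scipy), with proportions compared via the same t on 0/1 indicators. When
  both groups have zero variance the p-value is reported as not applicable.
* Percentages in rendered tables are rounded half-away-from-zero to one
  decimal, matching clinical-table convention; internal values stay exact.

## Synthetic data generator

The generator plants ground-truth cohort labels and emits the claims that
realize them, so recovery is checkable exactly. Default conditions:
n = 10,000 patients; label prevalences 8.4% broad-only, 0.8% MCA/ID/DD/E,
0.2% conservative (the published pediatric prevalence structure — Broad 9.4%
with its two subsets); 25% of labeled patients are planted as critically-ill
newborns (index uniform in days 0–28 plus a NICU stay from birth, log-normal
length, median ≈20 days). The newborn share is deliberately far above the
real-world share of the Broad cohort (~2.5%): at desk scale that share would
leave newborn cohort cells nearly empty, and the generator's purpose is to
exercise both populations.

Unlabeled patients receive only codes absent from the catalog — the control
definition is then exact, and any leakage is a bug, not noise. This also
means default synthetic controls have no NICU claims; a `control_nicu_rate`
knob plants short NICU stays in unlabeled newborns when nonzero control ICU
utilization is wanted.

Enrollment: one base span of 900–2400 days (newborns start at day 0; 30% of
others also start at birth); with probability 0.15 a geometric-length gap
(mean 90 days) splits the span, giving the continuous-enrollment filter a
real kill set. Planted index claims are emitted even when a gap overlaps
them — claims can be adjudicated outside eligibility — so every
planted-but-unrecovered label is attributable to the enrollment filter and
nothing else.

Costs are log-normal per claim (location 5.0/7.5/4.0 and scale 1.0/1.0/0.8
for outpatient/inpatient/pharmacy — roughly $250/$3,000/$80 medians).
Background utilization is Poisson at 0.8 claims per member-month. Labeled
patients' post-index claim rate and claim amounts are scaled by a multiplier
of 4 at month 0 decaying linearly to 1 by month 12, reproducing the
elevated-then-steady-state cost trajectory that the 30-day binning is meant
to detect. Conservative and MCA-labeled patients additionally acquire a
definite primary diagnosis 60–360 days post index with probability 0.3, so
the transition tables have signal.

What the generator does **not** emulate: real coding practice (miscoding,
code churn across the ICD-9→10 transition), correlated comorbidity
structure, insurance churn correlated with disease severity, denials or
coordination of benefits, and realistic covariate joint distributions.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under their stated definitions, not the field accuracy of the
phenotype on real claims.

## Numerical and reproducibility choices

All randomness derives from integer seeds through numpy's PCG64; the
pipeline derives one sub-seed per stage from the run seed (SeedSequence with
a CRC32 stage tag), so reruns with the same configuration are byte-identical
(no artifact embeds a timestamp). Degenerate inputs are defined rather than
accidental: empty cohorts yield NaN summaries, zero denominators render as
not-applicable, out-of-range covariate values clamp to boundary bins with a
logged warning, and a catalog may be loaded leniently (offending rows
dropped and logged, first occurrence wins) or strictly (abort).

Test problem sizes: oracle-equivalence suites compare against brute-force
enumeration on 1,000 random fixtures of ≤50 patients; recovery, matching
and cost properties run on one n = 10,000 synthetic population with complete
enrollment and one n = 4,000 population with planted gaps.

## Known limitations

* The fixture catalog is a schema demonstration; scientific use requires a
  clinically curated catalog file.
* ICD-9 and ICD-10 forms of one concept are independent catalog entries; no
  cross-walking or per-patient deduplication across the coding transition.
* Controls are global (no qualifying code ever); a patient cannot be a
  control for one population and a case in the other.
* Severity qualifiers (e.g. "moderate or severe" intellectual disability)
  must be encoded in the catalog's flag assignments; the pipeline has no
  severity logic of its own.
* Cost binning supports attrition-only disenrollment; re-enrollment after a
  gap re-enters later bins, which mirrors eligibility but complicates
  monotonicity of the contributing-n series.
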
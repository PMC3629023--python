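# Methods note

This note records the modelling decisions, numerical choices, and limits of
validity behind `nearmiss_audit`. The README gives the user-facing overview;
this is the reviewer-facing detail.

## 1. Case records and evaluability

`MaternalCaseRecord` is a flat pydantic model with one field per measurable
quantity the criteria reference (sustained systolic blood pressure, concurrent
pulse, fluids given, urine output over 4 h and 24 h, GCS, SpO₂ with duration,
platelets, bilirubin/creatinine/lactate/pH/PaO₂-FiO₂, intervention flags,
disease flags, transfused units, outcome). All fields except `case_id` and
`outcome` are optional; `blood_units_transfused` defaults to 0 because an
undocumented transfusion is a transfusion that did not happen, unlike an
unmeasured analyte.

A criterion is **evaluable** on a record iff *every* field in its
`required_fields` is populated. Unevaluable ⇒ not met. This is deliberately
strict for compound criteria: oliguria (refractory to fluids/diuretics AND
< 30 mL/h for 4 h OR < 400 mL/24 h) requires the refractoriness flag and both
urine measurements even though one disjunct could decide the answer. The
alternative — "evaluable if any deciding subset is present" — makes
evaluability depend on the values, not the documentation, and makes
completeness reporting ambiguous. The invariant `met ⇒ evaluable` is enforced
at the type level.

Classification: a dead woman is a **maternal death** regardless of criteria
("death from any cause" is the audit's reference condition); an alive woman
meeting ≥ 1 profile criterion is a **near miss**; otherwise non-case. The
criteria act as a diagnostic test only inside the validity analysis, where a
dead woman meeting no criterion is a false negative.

## 2. Criterion registry and profiles

All 29 criteria (25 WHO + ICU admission + eclampsia + sepsis + uterine
rupture) live in one registry of `CriterionDefinition`s: id, display name,
category, required fields, predicate, default parameters. Profiles are pure
data — a criterion-id subset plus parameter overrides — shipped as YAML
(`WHO-clinical`, `WHO`, `Haydom`). The only parametrised predicate in active
use is transfusion (`transfusion_threshold_units`: 5 for WHO, 1 for Haydom);
the sweep works by overriding this parameter, not by special-casing the
predicate. Unknown parameters raise `ConfigurationError` at evaluation time so
profile typos cannot silently revert to defaults.

Thresholds follow the WHO definitions: shock = sustained SBP < 90 mmHg with
pulse ≥ 120 bpm despite > 2 L of fluid; respiratory rate > 40 or < 6 /min;
clotting failure = no clot after 7 min; loss of consciousness = unconscious
≥ 12 h or GCS < 10; thrombocytopenia < 50 × 10⁹/L; SpO₂ < 90% for ≥ 60 min;
sepsis = clinical infection sign plus ≥ 3 of 4 SIRS components.

## 3. Indicators and rounding

With live births `n_LB`, deaths `n_MD`, near misses `n_MNM`:

- SMO ratio = 1000 · (n_MD + n_MNM) / n_LB
- case fatality rate (mortality index) = 100 · n_MD / (n_MD + n_MNM)

Ratios are computed in full double precision; only display values pass through
`round1`, a Decimal-based round-half-up to one decimal. This matters at the
margins the audit actually prints: 27.146 → 27.1, 12.903 → 12.9, 18.713 →
18.7. Python's banker's rounding (`round`) would disagree on half-way cases.

## 4. Diagnostic validity

The confusion table is built over **all delivered women**, not just the case
file: `tn` is inflated by `total_population − supplied cases`. With 9,471
women, 32 deaths and 248 positives under the local profile this yields
(tp, fp, fn, tn) = (32, 216, 0, 9223).

Binomial confidence intervals come from
`statsmodels.stats.proportion.proportion_confint`: Wilson score (default),
Wald (`normal`), Clopper–Pearson (`beta`). Wald is retained because audit
reports historically print it (it reproduces, e.g., a (99.4, 99.7) interval on
9394/9439 where Wilson gives slightly different bounds); Wilson is the better
default at extreme proportions. At k = 0 (k = n) the lower (upper) bound is
pinned to exactly 0 (100): analytically exact for all three methods, but the
closed-form Wilson evaluation otherwise leaves ~10⁻¹⁷ floating-point residue.
Wald bounds are clipped to [0, 100]. A zero-denominator metric (e.g. PPV with
no positives) is reported as `None`, never as NaN.

## 5. Transfusion threshold sweep

For each threshold t (strictly ascending, ≥ 1) the profile is deep-copied with
`transfusion_threshold_units = t` and the whole cohort re-classified. Reported
per row: positives, *sole-transfusion* cases (met-criteria set exactly
`{transfusion}`), validity against death over the full population, and the
case fatality rate among positives. On the reference cohort: 248 → 171 → 147
positives at t = 1, 2, 5; at t = 2, PPV 18.7% and specificity 98.5% at
unchanged 100% sensitivity. (The source audit prints "22.6% (32/171)" for
this PPV; 32/171 = 18.7%, and this package reports the computed value.)

## 6. Stepwise elimination

Input is a boolean case × criterion incidence matrix (all-zero rows rejected
by construction). Each step selects the criterion covering the most remaining
cases and removes those cases. Ties break by (current count, count in the
original full cohort, registry order). The original-count tie-break is what
the audit's own trace implies: at step 3 cardiac arrest and hysterectomy both
cover 8 remaining cases and cardiac arrest (26 vs 16 at baseline) is selected.
Criteria selected with count ≥ 1 are *independent*; criteria that fired at
baseline but reached zero before selection are *passive*; criteria that never
fired are *unused*. Independent counts partition the cases (they sum to the
cohort size).

The audit's printed grid ends with one simultaneous column excluding six
single-case criteria; the replay performs them as six sequential single-case
steps. The printed column equals the frequency snapshot before the first of
the six, so every printed cell is still checked verbatim.

## 7. Deterministic reference cohort

The audit's 92-case WHO incidence matrix is **reconstructed from the published
step marginals** (per-criterion counts at every elimination stage). The
selected criterion pins membership for the removed block; other criteria's
count decrements are assigned first-fit within the block. Co-occurrence is
therefore under-determined — the reconstruction is *a* matrix consistent with
every printed cell, not *the* historical matrix — but the elimination trace
depends only on the marginals (verified by a round-trip property test), so the
replay is exact. Infeasible marginals (a step removing more cases than the
selected criteria cover, or count decrements exceeding the removed block) are
rejected with named errors.

The remaining 156 local-profile cases are laid out deterministically:
disease-based and ICU overlays on fixed index ranges, a fixed transfusion-unit
plan (1/2/3 units) for WHO cases transfused below five units, sole-transfusion
recipients, and 55 cases covered exactly by the ICU/eclampsia/sepsis/uterine
rupture surplus. Field values are written through per-criterion *recipes*
(e.g. shock ⇒ SBP 80, pulse 132, fluids 3.0 L) merged worst-value-wins, and
every record is classified through the real predicates — there is no label
injection anywhere. Finally, vital-sign documentation is padded to the audit's
completeness targets (e.g. SBP documented for 183/248). Deaths are the first
32 case ids. The whole construction is RNG-free.

One figure in the source audit is internally inconsistent (the local-profile
per-stage counts do not sum to the stated cohort size); the local elimination
trace is therefore not a reproduction target, only the WHO trace is.

## 8. Synthetic cohort generator

`generate_cohort(SyntheticCohortConfig)` draws, per delivery, case status
(Bernoulli `p_case`), then for cases a latent severity z ~ N(0,1) shared
across criteria via a **Gaussian copula**: criterion c fires iff
ρz + √(1−ρ²)·u_c < Φ⁻¹(p_c), with loading ρ = `severity_loading` and marginal
prevalence p_c. This preserves the configured marginals exactly in expectation
while inducing severity-driven co-occurrence; death probability increases with
z, so dead cases carry more criteria — the qualitative structure the audit
reports. Defaults are calibrated to the reference cohort (prevalences from the
per-criterion frequency column, transfusion-unit distribution, sole-transfusion
fraction 77/108 among one-unit recipients, documented missingness rates).

Cases are realised through the same field recipes and re-verified positive
through the engine; if the copula leaves a case with no criterion, the
highest-prevalence criterion (ICU admission) is applied as a fallback.
Missingness never blanks a field required by a criterion the case is intended
to meet (a met criterion is by definition documented); other fields are
populated with normal values at rate 1 − missingness.

What the generator does **not** emulate: referral patterns, seasonality,
gestational-age structure, correlated missingness, or criterion co-occurrence
beyond the single latent factor. It is built for property tests and power
exploration, not epidemiological simulation.

## 9. Problem sizes and performance

Cohorts are ~10⁴ records with ~45 scalar fields; everything is pure-Python
per-record evaluation plus NumPy for the elimination matrix and copula, well
under a second per pipeline stage. The full test suite (193 tests, including
pooled-seed generator checks) runs in a few seconds; `scripts/acceptance.py`
in ~2 s.

## 10. Limitations

- Evaluability is binary per criterion; partial documentation of a compound
  criterion is treated the same as no documentation.
- The reference cohort reproduces all published margins but invents the
  within-case co-occurrence the source did not publish; analyses sensitive to
  co-occurrence beyond the WHO elimination marginals (e.g. WHO-clinical
  positives recomputed from the cohort rather than taken from the published
  confusion tables) can differ by a case or two.
- Confidence intervals assume independent Bernoulli outcomes; no clustering
  (e.g. by referral source) is modelled.
- The transfusion sweep varies one parameter; it does not explore joint
  re-parameterisations of the profile.
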
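# nearmiss-audit

Tools for auditing **severe maternal outcomes** (SMO) in a hospital delivery
cohort: encode maternal near-miss criteria as executable predicates, classify
cases, compute the WHO near-miss indicators with confidence intervals, assess
the diagnostic validity of a criteria set against maternal death, sweep the
red-cell transfusion threshold, and run the greedy stepwise-elimination
procedure that identifies which criteria independently contribute cases.

The package ships a deterministic reference cohort reproducing a 24-month
facility-based audit at Haydom Lutheran Hospital, a rural referral hospital in
northern Tanzania (9,471 delivered women; 248 severe maternal outcomes, of
which 32 maternal deaths), plus a synthetic-cohort generator for property
testing and power exploration.

## Background

A **maternal near miss** (MNM) is a woman who nearly died but survived a
complication during pregnancy, childbirth, or within 42 days of termination of
pregnancy. The WHO defines near miss through 25 criteria in three groups —
clinical signs of organ dysfunction (e.g. shock, gasping, loss of
consciousness), laboratory markers (e.g. thrombocytopenia, SpO₂ < 90% for
≥ 60 min), and management-based proxies (e.g. hysterectomy, ≥ 5 units of blood
transfused, intubation unrelated to anaesthesia).

In low-resource settings many laboratory analytes and interventions
(creatinine, lactate, dialysis, vasoactive drug infusion…) are simply not
available, so facilities adapt the criteria locally. This package encodes
three **criteria profiles** over one shared criterion registry:

| profile        | criteria | content |
|----------------|---------:|---------|
| `WHO-clinical` | 11       | clinical criteria only |
| `WHO`          | 25       | full WHO set (clinical + laboratory + management) |
| `Haydom`       | 21       | local adaptation: 11 clinical + 2 available labs (SpO₂, platelets) + 5 management criteria with the transfusion threshold lowered from 5 to 1 unit and ICU admission added + 3 disease-based criteria (eclampsia, sepsis, uterine rupture) |

A profile is data (YAML): a subset of registry criterion ids plus parameter
overrides such as `transfusion_threshold_units`. Criteria are only evaluated
when all their required fields are documented; an unevaluable criterion is
counted as not met.

## Model and indicators

For a cohort with `n_LB` live births, classified into maternal deaths (MD),
near misses (MNM = alive and meeting ≥ 1 criterion), and non-cases:

- **SMO ratio** = 1000 · (MD + MNM) / n_LB   (per 1,000 live births)
- **Case fatality rate / mortality index** = 100 · MD / (MD + MNM)   (%)

Diagnostic validity treats *meets ≥ 1 criterion* as the test and *maternal
death from any cause* as the condition, over **all delivered women** (women
not in the case file contribute true negatives). Sensitivity, specificity,
PPV and NPV carry two-sided binomial confidence intervals (Wilson score by
default; Wald and Clopper–Pearson available).

The **stepwise elimination** repeatedly selects the criterion met by the most
remaining cases, removes those cases, and recounts, until no cases remain.
Criteria selected while still covering ≥ 1 case contribute *independently*;
criteria whose counts fall to zero before selection are *passive* (their cases
always co-occur with stronger criteria).

## Worked example

Materialise the reference audit cohort and compute the indicators:

```bash
$ nearmiss-audit fixtures --name haydom-cohort --out-dir .
INFO nearmiss_audit: wrote 248 case records

$ nearmiss-audit indicators --in haydom_cohort.csv \
    --denominators haydom_denominators.json --profile Haydom
{
  "cfr_percent": 12.9,
  ...
  "n_MD": 32,
  "n_MNM": 216,
  "n_SMO": 248,
  "per_criterion_counts": {
    ...
    "icu_admission": 91,
    "shock": 51,
    "transfusion": 184,
    ...
  },
  "smo_ratio_per_1000_livebirths": 27.1
}
```

So the locally adapted criteria give an SMO ratio of **27.1 per 1,000 live
births** and a case fatality rate of **12.9%**. Validity of each profile
against maternal death over all 9,471 women:

```bash
$ nearmiss-audit validate --fixtures
{
  "Haydom": {
    "confusion": {"fn": 0, "fp": 216, "tn": 9223, "tp": 32},
    "metrics": {
      "sensitivity": {"estimate": 100.0, "lower": 89.3, ...},
      "specificity": {"estimate": 97.7, ...},
      "ppv": {"estimate": 12.9, ...},
      "npv": {"estimate": 100.0, ...}
    }
  },
  "WHO": { "confusion": {"fn": 0, "fp": 60, "tn": 9379, "tp": 32}, ... },
  "WHO-clinical": { ... }
}
```

All three profiles are fully sensitive for death; specificity falls from
99.5% (clinical criteria only) through 99.4% (full WHO) to 97.7% (local
adaptation), with PPV 41.6% → 34.8% → 12.9%.

Raising the local transfusion criterion from ≥ 1 to ≥ 2 units drops the sole
low-volume transfusion recipients:

```bash
$ nearmiss-audit sweep --in haydom_cohort.csv \
    --denominators haydom_denominators.json --thresholds 1,2,5
INFO nearmiss_audit: sweep threshold=1: 248 positives (102 sole-transfusion)
INFO nearmiss_audit: sweep threshold=2: 171 positives (25 sole-transfusion)
INFO nearmiss_audit: sweep threshold=5: 147 positives (1 sole-transfusion)
```

At two units the cohort shrinks to 171 positives with PPV **18.7%** and
specificity **98.5%**, at unchanged 100% sensitivity.

Stepwise elimination over the 92 cases meeting ≥ 1 full-WHO criterion:

```bash
$ nearmiss-audit eliminate --fixtures
INFO nearmiss_audit: eliminate: 12 steps over 92 cases; independent criteria:
  shock(51), loss_of_consciousness(13), cardiac_arrest(8), hysterectomy(8),
  thrombocytopenia(4), intubation(2), spo2_low(1), resp_rate_extreme(1),
  oliguria(1), clotting_failure(1), jaundice_preeclampsia(1), transfusion(1)
criterion	all n=92	step1 n=41	step2 n=28	...
shock	51	EXCL	-	...
cardiac_arrest	26	9	8	...
```

Excluding shock alone leaves 41 of 92 cases. Twelve criteria contribute
independently (summing to all 92 cases); CPR, gasping, stroke and
uncontrollable fits are passive; acute cyanosis never fired.

Synthetic cohorts for experimentation:

```bash
nearmiss-audit simulate --seed 7 --n-deliveries 5000 --out-dir sim/
nearmiss-audit classify --in sim/cohort.csv --profile WHO --out sim/classified.csv
```

The same pipeline is available as a Python API
(`nearmiss_audit.classify_cohort`, `compute_indicators`, `validity_metrics`,
`transfusion_threshold_sweep`, `stepwise_elimination`, `generate_cohort`, …);
see `docs/methods.md` for the formal definitions and numerical choices.

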
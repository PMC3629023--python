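"""Deterministic fixtures reproducing the Haydom audit's published counts.

These fixtures encode the cohort-level facts reported by the two-year
prospective audit at Haydom Lutheran Hospital, Tanzania (2009–2011): 9,471
deliveries, 9,136 live births, 248 criteria-positive cases under the locally
adapted profile (216 near misses + 32 deaths), the per-criterion frequency
column, the blood-transfusion unit structure, and the step-marginal grid of
the WHO-profile stepwise elimination.

Only marginal counts were published; the case-level co-occurrence needed to
materialise records is fixed by a documented deterministic assignment (no
RNG anywhere in this module):

* the 92 WHO-positive cases come from
  :func:`~nearmiss_audit.elimination.reconstruct_fixture_from_step_marginals`
  applied to the published elimination grid, so replaying the elimination
  reproduces every printed cell;
* ICU admissions (63), eclampsia (5), sepsis (20) and uterine rupture (13)
  among the WHO cases are overlaid on the lowest case indices;
* the 156 remaining cases are 77 sole one-unit transfusions, 22 sole
  two-unit, 2 sole three-unit, 25 one-unit recipients and 30 untransfused
  women; the last 55 are covered one-to-one by the remaining ICU (28),
  eclampsia (10), sepsis (10) and uterine rupture (7) occurrences;
* the 20 recipients of 3–4 units, bound only by a figure, are all placed at
  3 units;
* the 32 deaths are the first 32 cases (the shock block), so no profile has
  a false negative and no death sits among the 77 sole one-unit recipients.

Each woman who delivered but never became a case is a test-negative
survivor; she is represented by the population denominator rather than a
physical record.
"""

from __future__ import annotations

from typing import Optional

from ._synthesis import NORMAL_VALUES, apply_recipe
from .case_model import CohortDenominators, MaternalCaseRecord, Outcome
from .elimination import (
    IncidenceMatrix,
    StepMarginals,
    reconstruct_fixture_from_step_marginals,
)
from .validation import ConfusionTable

__all__ = [
    "N_DELIVERIES",
    "N_LIVE_BIRTHS",
    "audit_denominators",
    "audit_confusion_tables",
    "who_step_marginals",
    "who_incidence_matrix",
    "haydom_audit_cohort",
]

#: all women who delivered during the study period (validation denominator)
N_DELIVERIES = 9_471
N_LIVE_BIRTHS = 9_136
N_DEATHS = 32


def audit_denominators() -> CohortDenominators:
    return CohortDenominators(n_deliveries=N_DELIVERIES, n_live_births=N_LIVE_BIRTHS)


def audit_confusion_tables() -> dict[str, ConfusionTable]:
    """Published 2×2 tables (test = profile-positive, condition = death)."""
    return {
        "WHO-clinical": ConfusionTable(tp=32, fp=45, fn=0, tn=9_394),
        "WHO": ConfusionTable(tp=32, fp=60, fn=0, tn=9_379),
        "Haydom": ConfusionTable(tp=32, fp=216, fn=0, tn=9_223),
    }


# Published WHO-profile elimination grid: count of remaining cases carrying
# each criterion after k exclusion steps (column 0 = all 92 cases), None = dash.
_GRID: dict[str, list[Optional[int]]] = {
    "shock": [51, None, None, None, None, None, None, None],
    "cardiac_arrest": [26, 9, 8, None, None, None, None, None],
    "cpr": [19, 7, 6, 0, 0, 0, 0, 0],
    "spo2_low": [17, 8, 5, 2, 1, 1, 1, None],
    "hysterectomy": [16, 8, 8, 8, None, None, None, None],
    "loss_of_consciousness": [16, 13, None, None, None, None, None, None],
    "gasping": [15, 5, 4, 0, 0, 0, 0, 0],
    "intubation": [15, 6, 5, 2, 2, 2, None, None],
    "thrombocytopenia": [12, 5, 4, 4, 4, None, None, None],
    "resp_rate_extreme": [10, 7, 5, 3, 3, 1, 1, None],
    "oliguria": [4, 3, 1, 1, 1, 1, 1, None],
    "stroke": [4, 3, 1, 0, 0, 0, 0, 0],
    "clotting_failure": [3, 1, 1, 1, 1, 1, 1, None],
    "jaundice_preeclampsia": [3, 2, 1, 1, 1, 1, 1, None],
    "uncontrollable_fit": [3, 3, 1, 0, 0, 0, 0, 0],
    "transfusion": [2, 1, 1, 1, 1, 1, 1, None],
    "acute_cyanosis": [0, 0, 0, 0, 0, 0, 0, 0],
}

_N_REMAINING = [92, 41, 28, 20, 12, 8, 6, 0]

# the final six single-case criteria were excluded simultaneously in print
_SELECTED = [
    ["shock"],
    ["loss_of_consciousness"],
    ["cardiac_arrest"],
    ["hysterectomy"],
    ["thrombocytopenia"],
    ["intubation"],
    [
        "spo2_low",
        "resp_rate_extreme",
        "oliguria",
        "clotting_failure",
        "jaundice_preeclampsia",
        "transfusion",
    ],
]


def who_step_marginals() -> StepMarginals:
    """The published step-marginal grid of the WHO-profile elimination."""
    return StepMarginals(
        criterion_ids=list(_GRID),
        n_remaining=list(_N_REMAINING),
        counts={c: list(col) for c, col in _GRID.items()},
        selected=[list(s) for s in _SELECTED],
    )


def who_incidence_matrix() -> IncidenceMatrix:
    """92 cases × 17 WHO criteria reconstructed from the published grid."""
    return reconstruct_fixture_from_step_marginals(
        who_step_marginals(), case_id_prefix="who"
    )


# deterministic overlays on the 92 WHO cases (lowest indices first)
_WHO_ICU = 63
_WHO_ECLAMPSIA = 5
_WHO_SEPSIS = 20
_WHO_RUPTURE = 13

# documentation-completeness targets (records with the field populated);
# padding uses unremarkable values that satisfy no criterion
_COMPLETENESS_TARGETS = {
    "sbp_min_sustained_mmHg": 183,  # blood pressure measured in 74%
    "pulse_max_concurrent_bpm": 169,  # pulse noted in 68%
    "temp_extreme_C": 161,  # temperature noted in 65%
    "urine_output_mL_per_h_4h": 25,  # urinary output measured in 10%
}


def haydom_audit_cohort() -> tuple[list[MaternalCaseRecord], CohortDenominators]:
    """The deterministic 248-case audit cohort.

    Under the Haydom profile it classifies to 216 MNM + 32 MD and reproduces
    the published per-criterion frequency column and transfusion structure
    (108 one-unit recipients, 77 of them sole-criterion; 54 two-unit, 22
    sole; exactly two recipients of ≥5 units). Under the WHO profile exactly
    the 92 reconstructed cases remain positive.
    """
    matrix = who_incidence_matrix()
    col = {c: j for j, c in enumerate(matrix.criterion_ids)}
    rows: list[dict] = []

    # --- the 92 WHO-positive cases, fields driven by the matrix ---------
    for i in range(matrix.n_cases):
        values: dict = {}
        units = 0
        for c in matrix.criterion_ids:
            if not matrix.membership[i, col[c]]:
                continue
            if c == "transfusion":
                units = 5
            else:
                apply_recipe(values, c)
        if i < _WHO_ICU:
            apply_recipe(values, "icu_admission")
        if i < _WHO_ECLAMPSIA:
            apply_recipe(values, "eclampsia")
        elif i < _WHO_ECLAMPSIA + _WHO_SEPSIS:
            apply_recipe(values, "sepsis")
        elif i < _WHO_ECLAMPSIA + _WHO_SEPSIS + _WHO_RUPTURE:
            apply_recipe(values, "uterine_rupture")
        values["blood_units_transfused"] = units
        rows.append(values)

    # blood units for the 56 transfused WHO cases below the 5-unit mark:
    # 6 × 1 unit, 32 × 2 units, 18 × 3 units, by ascending case index
    who_unit_plan = [1] * 6 + [2] * 32 + [3] * 18
    k = 0
    for values in rows:
        if values["blood_units_transfused"] == 0 and k < len(who_unit_plan):
            values["blood_units_transfused"] = who_unit_plan[k]
            k += 1

    # --- the 156 cases positive only under the local profile ------------
    for _ in range(77):
        rows.append({"blood_units_transfused": 1})  # sole one-unit recipients
    for _ in range(22):
        rows.append({"blood_units_transfused": 2})  # sole two-unit recipients
    for _ in range(2):
        rows.append({"blood_units_transfused": 3})  # sole three-unit recipients
    extra = (
        ["icu_admission"] * 28
        + ["eclampsia"] * 10
        + ["sepsis"] * 10
        + ["uterine_rupture"] * 7
    )
    for idx, criterion in enumerate(extra):
        values: dict = {"blood_units_transfused": 1 if idx < 25 else 0}
        apply_recipe(values, criterion)
        rows.append(values)

    # --- documentation-completeness padding ------------------------------
    for fld, target in _COMPLETENESS_TARGETS.items():
        have = sum(1 for v in rows if fld in v)
        for v in rows:
            if have >= target:
                break
            if fld not in v:
                v[fld] = NORMAL_VALUES[fld]
                have += 1

    records = [
        MaternalCaseRecord(
            case_id=f"hlh-{i:03d}",
            outcome=Outcome.dead if i < N_DEATHS else Outcome.alive,
            **values,
        )
        for i, values in enumerate(rows)
    ]
    return records, audit_denominators()
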
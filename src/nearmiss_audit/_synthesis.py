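"""Field-value recipes that make criteria fire through the real predicates.

Synthetic cases are never labelled directly: a case intended to meet, say,
the shock criterion receives chart values (SBP 80 mmHg sustained, pulse
132/min, 3 L of fluids) that the criteria engine then evaluates like any real
record. Recipes merge monotonically — "worst value wins" — so a case can
carry several criteria without one recipe un-firing another: minimum-type
fields (blood pressure, platelets, saturation, GCS, urine output) take the
lower value, maximum-type fields (pulse, respiratory rate, fluids,
unconscious hours) the higher.
"""

from __future__ import annotations

from typing import Mapping

__all__ = ["CRITERION_RECIPES", "apply_recipe", "NORMAL_VALUES"]

# fields where the clinically worse value is the SMALLER one
_MIN_FIELDS = frozenset(
    {
        "sbp_min_sustained_mmHg",
        "spo2_min_pct",
        "platelets_per_mL",
        "gcs_min",
        "urine_output_mL_per_h_4h",
        "urine_output_mL_24h",
        "pao2_fio2_mmHg",
        "arterial_ph",
    }
)

#: criterion_id → field values that satisfy its predicate
CRITERION_RECIPES: dict[str, dict] = {
    "acute_cyanosis": {"acute_cyanosis": True},
    "gasping": {"gasping": True},
    "resp_rate_extreme": {"resp_rate_extreme_per_min": 44.0},
    "shock": {
        "sbp_min_sustained_mmHg": 80.0,
        "pulse_max_concurrent_bpm": 132.0,
        "fluids_given_L": 3.0,
    },
    "oliguria": {
        "urine_output_mL_per_h_4h": 20.0,
        "urine_output_mL_24h": 350.0,
        "oliguria_refractory": True,
    },
    "clotting_failure": {"clot_formation_minutes": 12.0},
    "loss_of_consciousness": {"unconscious_hours": 24.0, "gcs_min": 7},
    "cardiac_arrest": {"cardiac_arrest": True},
    "stroke": {"stroke": True},
    "uncontrollable_fit": {"uncontrollable_fit": True},
    "jaundice_preeclampsia": {
        "jaundice": True,
        "hypertension": True,
        "proteinuria": True,
    },
    "spo2_low": {"spo2_min_pct": 85.0, "spo2_low_duration_min": 90.0},
    "pao2_fio2_low": {"pao2_fio2_mmHg": 150.0},
    "creatinine_high": {"creatinine_umol_per_L": 350.0},
    "bilirubin_high": {"bilirubin_umol_per_L": 120.0},
    "ph_low": {"arterial_ph": 7.0},
    "lactate_high": {"lactate_mEq_per_mL": 6.0},
    "thrombocytopenia": {"platelets_per_mL": 30_000.0},
    "unconscious_ketoacids": {"ketoacids_in_urine": True, "unconscious_hours": 2.0},
    "icu_admission": {"icu_admission": True},
    "vasoactive_drugs": {"continuous_vasoactive_drugs": True},
    "hysterectomy": {"hysterectomy_infection_or_haemorrhage": True},
    # transfusion is driven by blood_units_transfused directly, not a recipe
    "intubation": {"intubation_minutes": 120.0, "intubation_anaesthesia_related": False},
    "dialysis": {"dialysis": True},
    "cpr": {"cpr_performed": True},
    "eclampsia": {"hypertension": True, "proteinuria": True, "fits": True},
    "sepsis": {
        "clinical_infection_sign": True,
        "temp_extreme_C": 39.2,
        "resp_rate_extreme_per_min": 24.0,
        "pulse_max_concurrent_bpm": 112.0,
        "wbc_10e9_per_L": 14.0,
    },
    "uterine_rupture": {"uterine_rupture": True},
}

#: unremarkable chart values used to pad documentation completeness; none of
#: them satisfies any criterion threshold
NORMAL_VALUES: dict[str, float] = {
    "sbp_min_sustained_mmHg": 112.0,
    "pulse_max_concurrent_bpm": 82.0,
    "temp_extreme_C": 37.0,
    "resp_rate_extreme_per_min": 18.0,
    "urine_output_mL_per_h_4h": 60.0,
    "urine_output_mL_24h": 1500.0,
    "wbc_10e9_per_L": 8.0,
    "platelets_per_mL": 250_000.0,
    "spo2_min_pct": 98.0,
    "spo2_low_duration_min": 0.0,
    "gcs_min": 15,
    "fluids_given_L": 0.5,
}


def apply_recipe(values: dict, criterion_id: str, recipe: Mapping | None = None) -> None:
    """Merge a criterion's recipe into ``values`` in place, worst value wins."""
    for fld, v in (recipe or CRITERION_RECIPES[criterion_id]).items():
        if isinstance(v, bool) or fld not in values:
            values[fld] = v
        elif fld in _MIN_FIELDS:
            values[fld] = min(values[fld], v)
        else:
            values[fld] = max(values[fld], v)
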
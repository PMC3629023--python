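"""Executable near-miss inclusion criteria and case classification.

The registry encodes the WHO maternal near-miss inclusion criteria (clinical,
laboratory-based and management-based) together with the additions used in
the locally adapted profile of a rural Tanzanian referral hospital (Haydom
Lutheran Hospital): admission to intensive care, and the disease-based
criteria eclampsia, sepsis and uterine rupture. Profiles select a subset of
criteria and may override numeric parameters — most importantly the blood
transfusion threshold, ≥5 units in the WHO set versus ≥1 unit locally, where
blood is scarce and there is no blood bank.

Evaluation semantics: a criterion is *evaluable* on a record only when every
field its predicate reads is populated; a missing required field makes the
criterion not met. This mirrors how criteria behave in practice on
incompletely documented charts — an unmeasured oxygen saturation can never
fire the saturation criterion — and guarantees ``met ⇒ evaluable``.

Case classification: a maternal death (MD) is any case with outcome ``dead``,
from any cause, regardless of which criteria fired; a maternal near miss
(MNM) is a survivor meeting at least one included criterion. The criteria act
as a diagnostic *test* only in the validation module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import yaml

from .case_model import MaternalCaseRecord, Outcome

__all__ = [
    "Category",
    "CriterionDefinition",
    "CriteriaProfile",
    "CriterionEvaluation",
    "CaseLabel",
    "CaseClassification",
    "ConfigurationError",
    "builtin_registry",
    "builtin_profile",
    "load_profile",
    "evaluate_criterion",
    "classify_case",
    "classify_cohort",
    "WHO_CRITERION_IDS",
    "WHO_CLINICAL_CRITERION_IDS",
    "HAYDOM_CRITERION_IDS",
]


class Category(str, enum.Enum):
    clinical = "clinical"
    laboratory = "laboratory"
    management = "management"
    disease = "disease"


Predicate = Callable[[MaternalCaseRecord, Mapping[str, float]], bool]


@dataclass(frozen=True)
class CriterionDefinition:
    """One executable inclusion criterion.

    ``required_fields`` lists every record field the predicate reads; all of
    them must be populated for the criterion to be evaluable. ``parameters``
    holds the named numeric thresholds with their defaults.
    """

    criterion_id: str
    display_name: str
    category: Category
    required_fields: tuple[str, ...]
    predicate: Predicate
    parameters: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CriterionEvaluation:
    criterion_id: str
    met: bool
    evaluable: bool

    def __post_init__(self):
        if self.met and not self.evaluable:
            raise ValueError("met criterion must be evaluable")


@dataclass
class CriteriaProfile:
    """A named, ordered selection of criteria with parameter overrides."""

    profile_name: str
    included_criteria: list[str]
    parameter_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.included_criteria)) != len(self.included_criteria):
            raise ConfigurationError(
                f"profile {self.profile_name!r}: duplicate criterion ids"
            )

    def validate_against(self, registry: Mapping[str, CriterionDefinition]) -> None:
        for cid in self.included_criteria:
            if cid not in registry:
                raise ConfigurationError(
                    f"profile {self.profile_name!r}: unknown criterion {cid!r}"
                )
        for cid, overrides in self.parameter_overrides.items():
            if cid not in registry:
                raise ConfigurationError(
                    f"profile {self.profile_name!r}: overrides for unknown criterion {cid!r}"
                )
            for pname in overrides:
                if pname not in registry[cid].parameters:
                    raise ConfigurationError(
                        f"profile {self.profile_name!r}: unknown parameter "
                        f"{pname!r} for criterion {cid!r}"
                    )
        thr = self.parameter_overrides.get("transfusion", {}).get(
            "transfusion_threshold_units"
        )
        if "transfusion" in self.included_criteria and thr is not None and thr < 1:
            raise ConfigurationError("transfusion_threshold_units must be ≥ 1")

    def params_for(
        self, definition: CriterionDefinition
    ) -> dict[str, float]:
        merged = dict(definition.parameters)
        merged.update(self.parameter_overrides.get(definition.criterion_id, {}))
        return merged

    def to_dict(self) -> dict:
        return {
            "profile_name": self.profile_name,
            "included_criteria": list(self.included_criteria),
            "parameter_overrides": {
                k: dict(v) for k, v in self.parameter_overrides.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CriteriaProfile":
        return cls(
            profile_name=data["profile_name"],
            included_criteria=list(data["included_criteria"]),
            parameter_overrides={
                k: dict(v) for k, v in data.get("parameter_overrides", {}).items()
            },
        )


class CaseLabel(str, enum.Enum):
    MD = "MD"
    MNM = "MNM"
    non_case = "non_case"


@dataclass(frozen=True)
class CaseClassification:
    case_id: str
    label: CaseLabel
    met_criteria: frozenset[str]


class ConfigurationError(ValueError):
    """Invalid profile, parameter or registry configuration."""


def _count_sirs(rec: MaternalCaseRecord, p: Mapping[str, float]) -> int:
    # systemic-inflammatory-response components of the sepsis definition
    return sum(
        (
            rec.temp_extreme_C > p["temp_high_C"]
            or rec.temp_extreme_C < p["temp_low_C"],
            rec.resp_rate_extreme_per_min > p["rr_sirs_per_min"],
            rec.pulse_max_concurrent_bpm > p["pulse_sirs_bpm"],
            rec.wbc_10e9_per_L > p["wbc_high_10e9_per_L"],
        )
    )


def _bool_criterion(cid: str, name: str, category: Category, fld: str) -> CriterionDefinition:
    return CriterionDefinition(
        criterion_id=cid,
        display_name=name,
        category=category,
        required_fields=(fld,),
        predicate=lambda r, p, _f=fld: bool(getattr(r, _f)),
    )


def builtin_registry() -> dict[str, CriterionDefinition]:
    """All built-in criterion definitions, in canonical order.

    Contains the 25 WHO criteria (11 clinical, 8 laboratory, 6 management)
    plus the 4 local additions (ICU admission, eclampsia, sepsis, uterine
    rupture). Criteria that a site cannot measure remain in the registry;
    they simply never become evaluable when their fields are never populated.
    """
    defs: list[CriterionDefinition] = [
        # ---- clinical -------------------------------------------------
        _bool_criterion("acute_cyanosis", "Acute cyanosis", Category.clinical, "acute_cyanosis"),
        _bool_criterion("gasping", "Gasping", Category.clinical, "gasping"),
        CriterionDefinition(
            "resp_rate_extreme",
            "Respiratory rate >40 or <6/min",
            Category.clinical,
            ("resp_rate_extreme_per_min",),
            lambda r, p: (
                r.resp_rate_extreme_per_min > p["rr_high_per_min"]
                or r.resp_rate_extreme_per_min < p["rr_low_per_min"]
            ),
            {"rr_high_per_min": 40.0, "rr_low_per_min": 6.0},
        ),
        CriterionDefinition(
            "shock",
            "Shock",
            Category.clinical,
            ("sbp_min_sustained_mmHg", "pulse_max_concurrent_bpm", "fluids_given_L"),
            # persistent severe hypotension: SBP <90 mmHg sustained 60 min with
            # pulse ≥120/min despite aggressive fluid replacement (>2 L)
            lambda r, p: (
                r.sbp_min_sustained_mmHg < p["sbp_mmHg"]
                and r.pulse_max_concurrent_bpm >= p["pulse_bpm"]
                and r.fluids_given_L > p["fluids_L"]
            ),
            {"sbp_mmHg": 90.0, "pulse_bpm": 120.0, "fluids_L": 2.0},
        ),
        CriterionDefinition(
            "oliguria",
            "Oliguria non responsive to fluids or diuretics",
            Category.clinical,
            ("urine_output_mL_per_h_4h", "urine_output_mL_24h", "oliguria_refractory"),
            lambda r, p: bool(r.oliguria_refractory)
            and (
                r.urine_output_mL_per_h_4h < p["urine_mL_per_h"]
                or r.urine_output_mL_24h < p["urine_mL_24h"]
            ),
            {"urine_mL_per_h": 30.0, "urine_mL_24h": 400.0},
        ),
        CriterionDefinition(
            "clotting_failure",
            "Failure to form clots",
            Category.clinical,
            ("clot_formation_minutes",),
            # bedside test: no clot from the IV site after 7–10 minutes; the
            # window is exposed as a parameter because only a range is defined
            lambda r, p: r.clot_formation_minutes > p["no_clot_after_min"],
            {"no_clot_after_min": 7.0},
        ),
        CriterionDefinition(
            "loss_of_consciousness",
            "Loss of consciousness lasting >12 h",
            Category.clinical,
            ("unconscious_hours", "gcs_min"),
            lambda r, p: (
                r.unconscious_hours > p["unconscious_hours_min"]
                or r.gcs_min < p["gcs_below"]
            ),
            {"unconscious_hours_min": 12.0, "gcs_below": 10.0},
        ),
        _bool_criterion("cardiac_arrest", "Cardiac arrest", Category.clinical, "cardiac_arrest"),
        _bool_criterion("stroke", "Stroke", Category.clinical, "stroke"),
        _bool_criterion(
            "uncontrollable_fit",
            "Uncontrollable fit/total paralysis",
            Category.clinical,
            "uncontrollable_fit",
        ),
        CriterionDefinition(
            "jaundice_preeclampsia",
            "Jaundice in the presence of pre-eclampsia",
            Category.clinical,
            ("jaundice", "hypertension", "proteinuria"),
            lambda r, p: bool(r.jaundice and r.hypertension and r.proteinuria),
        ),
        # ---- laboratory -----------------------------------------------
        CriterionDefinition(
            "spo2_low",
            "Oxygen saturation <90% for ≥60 minutes",
            Category.laboratory,
            ("spo2_min_pct", "spo2_low_duration_min"),
            lambda r, p: (
                r.spo2_min_pct < p["spo2_pct"]
                and r.spo2_low_duration_min >= p["duration_min"]
            ),
            {"spo2_pct": 90.0, "duration_min": 60.0},
        ),
        CriterionDefinition(
            "pao2_fio2_low",
            "PaO2/FiO2 <200 mmHg",
            Category.laboratory,
            ("pao2_fio2_mmHg",),
            lambda r, p: r.pao2_fio2_mmHg < p["pao2_fio2_mmHg"],
            {"pao2_fio2_mmHg": 200.0},
        ),
        CriterionDefinition(
            "creatinine_high",
            "Creatinine ≥300 µmol/l",
            Category.laboratory,
            ("creatinine_umol_per_L",),
            lambda r, p: r.creatinine_umol_per_L >= p["creatinine_umol_per_L"],
            {"creatinine_umol_per_L": 300.0},
        ),
        CriterionDefinition(
            "bilirubin_high",
            "Bilirubin >100 µmol/l",
            Category.laboratory,
            ("bilirubin_umol_per_L",),
            lambda r, p: r.bilirubin_umol_per_L > p["bilirubin_umol_per_L"],
            {"bilirubin_umol_per_L": 100.0},
        ),
        CriterionDefinition(
            "ph_low",
            "pH <7.1",
            Category.laboratory,
            ("arterial_ph",),
            lambda r, p: r.arterial_ph < p["ph"],
            {"ph": 7.1},
        ),
        CriterionDefinition(
            "lactate_high",
            "Lactate >5 mEq/ml",
            Category.laboratory,
            ("lactate_mEq_per_mL",),
            lambda r, p: r.lactate_mEq_per_mL > p["lactate_mEq_per_mL"],
            {"lactate_mEq_per_mL": 5.0},
        ),
        CriterionDefinition(
            "thrombocytopenia",
            "Acute thrombocytopenia (<50,000 platelets/ml)",
            Category.laboratory,
            ("platelets_per_mL",),
            lambda r, p: r.platelets_per_mL < p["platelets_per_mL"],
            {"platelets_per_mL": 50_000.0},
        ),
        CriterionDefinition(
            "unconscious_ketoacids",
            "Loss of consciousness and ketoacids in urine",
            Category.laboratory,
            ("unconscious_hours", "ketoacids_in_urine"),
            lambda r, p: bool(r.ketoacids_in_urine) and r.unconscious_hours > 0,
        ),
        # ---- management -----------------------------------------------
        _bool_criterion(
            "icu_admission",
            "Admission to intensive care unit",
            Category.management,
            "icu_admission",
        ),
        _bool_criterion(
            "vasoactive_drugs",
            "Use of continuous vasoactive drugs",
            Category.management,
            "continuous_vasoactive_drugs",
        ),
        _bool_criterion(
            "hysterectomy",
            "Hysterectomy following infection or haemorrhage",
            Category.management,
            "hysterectomy_infection_or_haemorrhage",
        ),
        CriterionDefinition(
            "transfusion",
            "Transfusion of blood",
            Category.management,
            ("blood_units_transfused",),
            lambda r, p: r.blood_units_transfused >= p["transfusion_threshold_units"],
            {"transfusion_threshold_units": 5.0},
        ),
        CriterionDefinition(
            "intubation",
            "Intubation and ventilation ≥60 minutes not related to anaesthesia",
            Category.management,
            ("intubation_minutes", "intubation_anaesthesia_related"),
            lambda r, p: (
                r.intubation_minutes >= p["duration_min"]
                and not r.intubation_anaesthesia_related
            ),
            {"duration_min": 60.0},
        ),
        CriterionDefinition(
            "dialysis",
            "Dialysis for acute renal failure",
            Category.management,
            ("dialysis",),
            lambda r, p: bool(r.dialysis),
        ),
        _bool_criterion(
            "cpr", "Cardio-pulmonary resuscitation", Category.management, "cpr_performed"
        ),
        # ---- disease-based --------------------------------------------
        CriterionDefinition(
            "eclampsia",
            "Eclampsia",
            Category.disease,
            ("hypertension", "proteinuria", "fits"),
            lambda r, p: bool(r.hypertension and r.proteinuria and r.fits),
        ),
        CriterionDefinition(
            "sepsis",
            "Sepsis or severe systemic infection",
            Category.disease,
            (
                "clinical_infection_sign",
                "temp_extreme_C",
                "resp_rate_extreme_per_min",
                "pulse_max_concurrent_bpm",
                "wbc_10e9_per_L",
            ),
            # clinical sign of infection plus ≥3 of: temp >38 or <36 °C,
            # respiration >20/min, pulse >90/min, WBC >12
            lambda r, p: bool(r.clinical_infection_sign)
            and _count_sirs(r, p) >= int(p["sirs_min_components"]),
            {
                "temp_high_C": 38.0,
                "temp_low_C": 36.0,
                "rr_sirs_per_min": 20.0,
                "pulse_sirs_bpm": 90.0,
                "wbc_high_10e9_per_L": 12.0,
                "sirs_min_components": 3.0,
            },
        ),
        _bool_criterion(
            "uterine_rupture", "Uterine rupture", Category.disease, "uterine_rupture"
        ),
    ]
    registry = {d.criterion_id: d for d in defs}
    for d in registry.values():
        unknown = set(d.required_fields) - set(MaternalCaseRecord.model_fields)
        if unknown:  # pragma: no cover - registry self-check
            raise ConfigurationError(
                f"criterion {d.criterion_id!r} reads unknown fields {sorted(unknown)}"
            )
    return registry


WHO_CLINICAL_CRITERION_IDS: tuple[str, ...] = (
    "acute_cyanosis",
    "gasping",
    "resp_rate_extreme",
    "shock",
    "oliguria",
    "clotting_failure",
    "loss_of_consciousness",
    "cardiac_arrest",
    "stroke",
    "uncontrollable_fit",
    "jaundice_preeclampsia",
)

WHO_CRITERION_IDS: tuple[str, ...] = WHO_CLINICAL_CRITERION_IDS + (
    "spo2_low",
    "pao2_fio2_low",
    "creatinine_high",
    "bilirubin_high",
    "ph_low",
    "lactate_high",
    "thrombocytopenia",
    "unconscious_ketoacids",
    "vasoactive_drugs",
    "hysterectomy",
    "transfusion",
    "intubation",
    "dialysis",
    "cpr",
)

HAYDOM_CRITERION_IDS: tuple[str, ...] = WHO_CLINICAL_CRITERION_IDS + (
    "spo2_low",
    "thrombocytopenia",
    "icu_admission",
    "hysterectomy",
    "transfusion",
    "intubation",
    "cpr",
    "eclampsia",
    "sepsis",
    "uterine_rupture",
)


def _profiles_dir() -> Path:
    return Path(__file__).parent / "profiles"


def load_profile(source: Union[str, Path, dict]) -> CriteriaProfile:
    """Load a profile from a dict, a YAML/JSON file path, or a built-in name."""
    if isinstance(source, dict):
        return CriteriaProfile.from_dict(source)
    p = Path(source)
    if not p.exists():
        builtin = _profiles_dir() / f"{source}.yaml"
        if builtin.exists():
            p = builtin
        else:
            raise ConfigurationError(f"no such profile file or built-in name: {source!r}")
    with p.open(encoding="utf-8") as fh:
        return CriteriaProfile.from_dict(yaml.safe_load(fh))


def builtin_profile(name: str) -> CriteriaProfile:
    """Built-in profiles: ``WHO``, ``WHO-clinical``, ``Haydom``."""
    return load_profile(name)


def evaluate_criterion(
    record: MaternalCaseRecord,
    definition: CriterionDefinition,
    params: Optional[Mapping[str, float]] = None,
) -> CriterionEvaluation:
    """Evaluate one criterion on one record.

    ``params`` overrides the definition's defaults; an unknown parameter name
    is a configuration error. A missing required field makes the evaluation
    ``evaluable=False, met=False``.
    """
    merged = dict(definition.parameters)
    if params:
        unknown = set(params) - set(definition.parameters)
        if unknown:
            raise ConfigurationError(
                f"criterion {definition.criterion_id!r}: unknown parameters {sorted(unknown)}"
            )
        merged.update(params)
    populated = record.populated_fields()
    evaluable = all(f in populated for f in definition.required_fields)
    met = bool(definition.predicate(record, merged)) if evaluable else False
    return CriterionEvaluation(definition.criterion_id, met=met, evaluable=evaluable)


def classify_case(
    record: MaternalCaseRecord,
    profile: CriteriaProfile,
    registry: Mapping[str, CriterionDefinition],
) -> CaseClassification:
    """Classify one case as MD / MNM / non-case under a profile.

    A death is MD whatever the criteria say (deaths are included from any
    cause); a survivor is MNM iff she meets at least one included criterion.
    ``met_criteria`` is reported for deaths too, because validation treats
    criteria-positivity and death independently.
    """
    met = frozenset(
        cid
        for cid in profile.included_criteria
        if evaluate_criterion(record, registry[cid], profile.params_for(registry[cid])).met
    )
    if record.outcome is Outcome.dead:
        label = CaseLabel.MD
    elif met:
        label = CaseLabel.MNM
    else:
        label = CaseLabel.non_case
    return CaseClassification(record.case_id, label, met)


def classify_cohort(
    records: Sequence[MaternalCaseRecord],
    profile: CriteriaProfile,
    registry: Mapping[str, CriterionDefinition],
) -> tuple[list[CaseClassification], dict[str, int]]:
    """Element-wise classification plus {n_MD, n_MNM, n_non_case} counts."""
    profile.validate_against(registry)
    classifications = [classify_case(r, profile, registry) for r in records]
    counts = {"n_MD": 0, "n_MNM": 0, "n_non_case": 0}
    for c in classifications:
        counts[f"n_{c.label.value}"] += 1
    return classifications, counts
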
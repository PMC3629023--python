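"""Case-level domain types and bit-exact CSV interchange.

A :class:`MaternalCaseRecord` is an episode summary of one woman's hospital
stay: measurements, interventions, diagnoses and her vital outcome at
discharge (or within 42 days of termination of pregnancy). Heavy missingness
is the norm in the charts these records are abstracted from — in the source
setting oxygen saturation was noted for fewer than 5% of severe cases — so
"missing" is a first-class state distinct from "observed absent", and the CSV
representation (empty cell = missing) round-trips records without loss.
"""

from __future__ import annotations

import csv
import enum
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "Outcome",
    "PregnancyTiming",
    "MaternalCaseRecord",
    "CohortDenominators",
    "CSV_COLUMNS",
    "CohortParseError",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_denominators_json",
    "write_denominators_json",
]


class Outcome(str, enum.Enum):
    """Vital status at discharge / 42 days after termination of pregnancy."""

    alive = "alive"
    dead = "dead"


class PregnancyTiming(str, enum.Enum):
    pregnant = "pregnant"
    intrapartum = "intrapartum"
    postpartum_42d = "postpartum_42d"


class MaternalCaseRecord(BaseModel):
    """One woman's episode summary.

    All measurement and intervention fields are optional: ``None`` means the
    quantity was never recorded. The only mandatory fields are ``case_id``
    and ``outcome``. ``blood_units_transfused`` defaults to 0 because a
    transfusion is an affirmative event — an empty cell means no transfusion,
    not an unknown one.
    """

    model_config = ConfigDict(validate_assignment=True, extra="forbid")

    case_id: str
    outcome: Outcome
    pregnancy_timing: Optional[PregnancyTiming] = None

    # circulatory dysfunction / shock episode (pre-summarised from the chart)
    sbp_min_sustained_mmHg: Optional[float] = None
    pulse_max_concurrent_bpm: Optional[float] = None
    fluids_given_L: Optional[float] = Field(default=None, ge=0)

    # respiratory
    resp_rate_extreme_per_min: Optional[float] = None
    spo2_min_pct: Optional[float] = Field(default=None, ge=0, le=100)
    spo2_low_duration_min: Optional[float] = Field(default=None, ge=0)
    acute_cyanosis: Optional[bool] = None
    gasping: Optional[bool] = None

    # infection work-up
    temp_extreme_C: Optional[float] = None
    wbc_10e9_per_L: Optional[float] = Field(default=None, ge=0)
    clinical_infection_sign: Optional[bool] = None

    # neurological
    unconscious_hours: Optional[float] = Field(default=None, ge=0)
    gcs_min: Optional[int] = Field(default=None, ge=3, le=15)
    stroke: Optional[bool] = None
    uncontrollable_fit: Optional[bool] = None
    fits: Optional[bool] = None

    # renal
    urine_output_mL_per_h_4h: Optional[float] = Field(default=None, ge=0)
    urine_output_mL_24h: Optional[float] = Field(default=None, ge=0)
    oliguria_refractory: Optional[bool] = None

    # coagulation / haematology
    clot_formation_minutes: Optional[float] = Field(default=None, ge=0)
    platelets_per_mL: Optional[float] = Field(default=None, ge=0)

    # hypertensive disease
    hypertension: Optional[bool] = None
    proteinuria: Optional[bool] = None
    jaundice: Optional[bool] = None

    # catastrophic events
    cardiac_arrest: Optional[bool] = None
    uterine_rupture: Optional[bool] = None

    # laboratory analytes unavailable in many low-resource settings; kept so
    # the full WHO laboratory criteria remain evaluable where they exist
    pao2_fio2_mmHg: Optional[float] = Field(default=None, ge=0)
    creatinine_umol_per_L: Optional[float] = Field(default=None, ge=0)
    bilirubin_umol_per_L: Optional[float] = Field(default=None, ge=0)
    arterial_ph: Optional[float] = Field(default=None, ge=0, le=14)
    lactate_mEq_per_mL: Optional[float] = Field(default=None, ge=0)
    ketoacids_in_urine: Optional[bool] = None

    # management
    blood_units_transfused: int = Field(default=0, ge=0)
    hysterectomy_infection_or_haemorrhage: Optional[bool] = None
    cpr_performed: Optional[bool] = None
    icu_admission: Optional[bool] = None
    dialysis: Optional[bool] = None
    continuous_vasoactive_drugs: Optional[bool] = None
    intubation_minutes: Optional[float] = Field(default=None, ge=0)
    intubation_anaesthesia_related: Optional[bool] = None

    def populated_fields(self) -> set[str]:
        """Names of fields carrying an observed value.

        ``blood_units_transfused`` is always populated (it defaults to an
        affirmative 0); every other optional field counts only when not None.
        """
        out = {"case_id", "outcome", "blood_units_transfused"}
        for name in type(self).model_fields:
            if name in out:
                continue
            if getattr(self, name) is not None:
                out.add(name)
        return out


class CohortDenominators(BaseModel):
    """Cohort-level denominators: deliveries and live births in the period."""

    model_config = ConfigDict(extra="forbid")

    n_deliveries: int = Field(gt=0)
    n_live_births: int = Field(gt=0)


#: Canonical CSV column order. Fixed — no dialect auto-detection.
CSV_COLUMNS: tuple[str, ...] = tuple(MaternalCaseRecord.model_fields)

_BOOL_FIELDS = frozenset(
    name
    for name, f in MaternalCaseRecord.model_fields.items()
    if "bool" in repr(f.annotation)
)
_INT_FIELDS = frozenset({"gcs_min", "blood_units_transfused"})
_ENUM_FIELDS = {"outcome": Outcome, "pregnancy_timing": PregnancyTiming}


class CohortParseError(ValueError):
    """Raised when a cohort CSV cell or header cannot be parsed."""


def _parse_cell(name: str, raw: str, row_number: int):
    if raw == "":
        return None
    if name == "case_id":
        return raw
    if name in _ENUM_FIELDS:
        try:
            return _ENUM_FIELDS[name](raw)
        except ValueError:
            raise CohortParseError(
                f"row {row_number}, column {name!r}: invalid value {raw!r}"
            ) from None
    if name in _BOOL_FIELDS:
        if raw in ("0", "1"):
            return raw == "1"
        raise CohortParseError(
            f"row {row_number}, column {name!r}: boolean cell must be 0 or 1, got {raw!r}"
        )
    try:
        return int(raw) if name in _INT_FIELDS else float(raw)
    except ValueError:
        raise CohortParseError(
            f"row {row_number}, column {name!r}: malformed number {raw!r}"
        ) from None


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)  # repr round-trips doubles exactly
    return str(value)


def read_cohort_csv(path: Union[str, Path]) -> list[MaternalCaseRecord]:
    """Read a cohort CSV (UTF-8, header required) into records.

    Empty cells map to missing; booleans are ``0``/``1``; numbers use a ``.``
    decimal separator regardless of locale. Row order is preserved. Unknown
    or missing header columns are rejected.
    """
    path = Path(path)
    records: list[MaternalCaseRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file, header row required") from None
        if tuple(header) != CSV_COLUMNS:
            unknown = sorted(set(header) - set(CSV_COLUMNS))
            missing = sorted(set(CSV_COLUMNS) - set(header))
            raise CohortParseError(
                f"{path}: header does not match the cohort schema "
                f"(unknown columns: {unknown}; missing columns: {missing})"
            )
        for row_number, row in enumerate(reader, start=2):
            if len(row) != len(CSV_COLUMNS):
                raise CohortParseError(
                    f"row {row_number}: expected {len(CSV_COLUMNS)} cells, got {len(row)}"
                )
            data = {}
            for name, raw in zip(CSV_COLUMNS, row):
                value = _parse_cell(name, raw, row_number)
                if value is not None:
                    data[name] = value
            if "outcome" not in data:
                raise CohortParseError(f"row {row_number}: 'outcome' is required")
            if "case_id" not in data:
                raise CohortParseError(f"row {row_number}: 'case_id' is required")
            records.append(MaternalCaseRecord(**data))
    return records


def write_cohort_csv(
    records: list[MaternalCaseRecord], path: Union[str, Path]
) -> None:
    """Write records to CSV so that :func:`read_cohort_csv` recovers them bit-exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(_format_cell(getattr(rec, name)) for name in CSV_COLUMNS)


def read_denominators_json(path: Union[str, Path]) -> CohortDenominators:
    import json

    with Path(path).open(encoding="utf-8") as fh:
        return CohortDenominators(**json.load(fh))


def write_denominators_json(
    denominators: CohortDenominators, path: Union[str, Path]
) -> None:
    import json

    Path(path).write_text(
        json.dumps(denominators.model_dump(), indent=2) + "\n", encoding="utf-8"
    )
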
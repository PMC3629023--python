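"""Cohort-level near-miss indicators and the transfusion-threshold sweep.

Indicators follow the standard near-miss audit definitions: the severe
maternal outcome (SMO) count is MNM + MD; the SMO ratio is SMO per 1,000 live
births; the case fatality rate (CFR, also called the mortality index) is
MD / SMO. All quantities are kept at full precision internally; the printed
one-decimal values are produced by :func:`round1` (round half up) only at
presentation time.

The transfusion-threshold sweep re-classifies the cohort with the blood
transfusion criterion's unit threshold overridden, because that single
parameter drives most of the difference between a ≥1-unit local profile and
the ≥5-unit WHO profile: many one-unit recipients have no other inclusion
criterion at all and drop out as soon as the threshold is raised.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .case_model import CohortDenominators, MaternalCaseRecord
from .criteria import (
    CaseClassification,
    CaseLabel,
    CriteriaProfile,
    CriterionDefinition,
    classify_cohort,
)
from .validation import CIMethod, ValidityMetrics, build_confusion, validity_metrics

__all__ = [
    "IndicatorReport",
    "ThresholdSweepRow",
    "round1",
    "compute_indicators",
    "criterion_frequency_table",
    "completeness_report",
    "transfusion_threshold_sweep",
]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (27.146 → 27.1, 12.95 → 13.0)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class IndicatorReport:
    n_MNM: int
    n_MD: int
    smo_ratio_per_1000_livebirths: float
    cfr_percent: Optional[float]
    per_criterion_counts: dict[str, int] = field(default_factory=dict)
    completeness: dict[str, float] = field(default_factory=dict)

    @property
    def n_SMO(self) -> int:
        return self.n_MNM + self.n_MD

    def to_dict(self, rounded: bool = False) -> dict:
        smo = self.smo_ratio_per_1000_livebirths
        cfr = self.cfr_percent
        if rounded:
            smo = round1(smo)
            cfr = None if cfr is None else round1(cfr)
        return {
            "n_MNM": self.n_MNM,
            "n_MD": self.n_MD,
            "n_SMO": self.n_SMO,
            "smo_ratio_per_1000_livebirths": smo,
            "cfr_percent": cfr,
            "per_criterion_counts": dict(self.per_criterion_counts),
            "completeness": dict(self.completeness),
        }


@dataclass
class ThresholdSweepRow:
    threshold_units: int
    n_positives: int
    n_sole_transfusion_cases: int
    cfr_percent: Optional[float]
    validity: ValidityMetrics

    def to_dict(self) -> dict:
        return {
            "threshold_units": self.threshold_units,
            "n_positives": self.n_positives,
            "n_sole_transfusion_cases": self.n_sole_transfusion_cases,
            "cfr_percent": self.cfr_percent,
            "validity": self.validity.to_dict(),
        }


def compute_indicators(
    classifications: Sequence[CaseClassification],
    denominators: CohortDenominators,
    per_criterion_counts: Optional[Mapping[str, int]] = None,
    completeness: Optional[Mapping[str, float]] = None,
) -> IndicatorReport:
    """Severe-maternal-outcome indicators for a classified cohort."""
    n_md = sum(c.label is CaseLabel.MD for c in classifications)
    n_mnm = sum(c.label is CaseLabel.MNM for c in classifications)
    n_smo = n_md + n_mnm
    smo_ratio = 1000.0 * n_smo / denominators.n_live_births
    cfr = 100.0 * n_md / n_smo if n_smo > 0 else None
    return IndicatorReport(
        n_MNM=n_mnm,
        n_MD=n_md,
        smo_ratio_per_1000_livebirths=smo_ratio,
        cfr_percent=cfr,
        per_criterion_counts=dict(per_criterion_counts or {}),
        completeness=dict(completeness or {}),
    )


def criterion_frequency_table(
    classifications: Sequence[CaseClassification],
    profile: CriteriaProfile,
) -> dict[str, int]:
    """How often each included criterion fired among positive (MNM+MD) cases.

    A case increments every criterion it meets, so the column can sum to more
    than the number of cases.
    """
    counts = {cid: 0 for cid in profile.included_criteria}
    for c in classifications:
        if c.label is CaseLabel.non_case:
            continue
        for cid in c.met_criteria:
            counts[cid] += 1
    return counts


def completeness_report(
    records: Sequence[MaternalCaseRecord],
    fields: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Fraction of records with each field populated (over all supplied records)."""
    names = list(fields) if fields is not None else list(MaternalCaseRecord.model_fields)
    if not records:
        return {name: 0.0 for name in names}
    populated = [r.populated_fields() for r in records]
    return {
        name: sum(name in p for p in populated) / len(records) for name in names
    }


def _with_transfusion_threshold(
    profile: CriteriaProfile, threshold: int
) -> CriteriaProfile:
    modified = copy.deepcopy(profile)
    modified.parameter_overrides.setdefault("transfusion", {})[
        "transfusion_threshold_units"
    ] = float(threshold)
    return modified


def transfusion_threshold_sweep(
    records: Sequence[MaternalCaseRecord],
    profile: CriteriaProfile,
    registry: Mapping[str, CriterionDefinition],
    thresholds: Sequence[int],
    total_population: int,
    ci_method: CIMethod | str = CIMethod.wilson,
    alpha: float = 0.05,
) -> list[ThresholdSweepRow]:
    """Re-classify the cohort at each transfusion threshold.

    For every threshold the profile's transfusion parameter is overridden,
    positives are recounted, and validity against death is recomputed over
    the full delivered population. ``n_sole_transfusion_cases`` counts the
    positives whose only met criterion is the transfusion itself — the cases
    that vanish as soon as the threshold climbs past their unit count.
    """
    if list(thresholds) != sorted(thresholds) or any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be ascending integers ≥ 1")
    if "transfusion" not in profile.included_criteria:
        raise ValueError("profile does not include the transfusion criterion")
    rows = []
    for t in thresholds:
        modified = _with_transfusion_threshold(profile, t)
        classifications, _ = classify_cohort(records, modified, registry)
        test_flags = [bool(c.met_criteria) for c in classifications]
        death_flags = [c.label is CaseLabel.MD for c in classifications]
        n_pos = sum(test_flags)
        n_sole = sum(
            1
            for c in classifications
            if c.met_criteria == frozenset({"transfusion"})
        )
        ct = build_confusion(test_flags, death_flags, total_population)
        cfr = 100.0 * ct.tp / n_pos if n_pos > 0 else None
        rows.append(
            ThresholdSweepRow(
                threshold_units=t,
                n_positives=n_pos,
                n_sole_transfusion_cases=n_sole,
                cfr_percent=cfr,
                validity=validity_metrics(ct, ci_method, alpha),
            )
        )
    return rows
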
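"""Synthetic cohort generator with latent-severity criterion co-occurrence.

The generator emulates the statistical structure the audit pipeline assumes:
a delivery cohort in which a small fraction of women become criteria-positive
cases, criteria co-occur because they share an underlying illness severity,
transfusion units follow a highly skewed distribution in which many one-unit
recipients have no other criterion, and chart documentation is incomplete.

Criteria and death are sampled through a Gaussian copula: case ``i`` has a
latent severity :math:`z_i \\sim N(0,1)`, and criterion ``c`` fires when
:math:`\\rho z_i + \\sqrt{1-\\rho^2}\\,u_{ic} < \\Phi^{-1}(p_c)` with
independent :math:`u_{ic} \\sim N(0,1)`. The marginal probability of each
criterion (and of death) is therefore *exactly* the configured value while
sicker cases accumulate more criteria and die more often. Cases are realised
as chart values through the criteria engine's own predicates — never by
injecting labels — and missingness is applied afterwards, except that a field
required by a criterion the case actually met is never blanked (a criterion
counted as met was, by definition, documented).

Defaults reproduce the magnitudes of the source audit: 9,471 deliveries,
case probability 248/9,471, death probability 32/248 among cases, criterion
prevalences from the published frequency column, and a transfusion-unit
distribution with 77/108 of one-unit recipients having no other criterion.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.stats import norm

from ._synthesis import NORMAL_VALUES, apply_recipe
from .case_model import CohortDenominators, MaternalCaseRecord, Outcome
from .criteria import builtin_registry

__all__ = ["SyntheticCohortConfig", "generate_cohort"]

# published frequency column over 248 positive cases (transfusion handled
# through the unit distribution instead)
_DEFAULT_PREVALENCE = {
    "gasping": 15 / 248,
    "resp_rate_extreme": 10 / 248,
    "shock": 51 / 248,
    "oliguria": 4 / 248,
    "clotting_failure": 3 / 248,
    "loss_of_consciousness": 16 / 248,
    "cardiac_arrest": 26 / 248,
    "stroke": 4 / 248,
    "uncontrollable_fit": 3 / 248,
    "jaundice_preeclampsia": 3 / 248,
    "spo2_low": 17 / 248,
    "thrombocytopenia": 12 / 248,
    "icu_admission": 91 / 248,
    "hysterectomy": 16 / 248,
    "intubation": 15 / 248,
    "cpr": 19 / 248,
    "eclampsia": 15 / 248,
    "sepsis": 30 / 248,
    "uterine_rupture": 20 / 248,
}

# units 0,1,2,3,4,5 among the 248 cases
_DEFAULT_TRANSFUSION_DIST = (64 / 248, 108 / 248, 54 / 248, 20 / 248, 0.0, 2 / 248)

# observed chart-documentation gaps (fraction unrecorded)
_DEFAULT_MISSINGNESS = {
    "sbp_min_sustained_mmHg": 1 - 183 / 248,
    "pulse_max_concurrent_bpm": 1 - 169 / 248,
    "temp_extreme_C": 1 - 161 / 248,
    "urine_output_mL_per_h_4h": 1 - 25 / 248,
    "urine_output_mL_24h": 1 - 25 / 248,
    "spo2_min_pct": 1 - 10 / 248,
    "spo2_low_duration_min": 1 - 10 / 248,
    "wbc_10e9_per_L": 1 - 155 / 248,
    "platelets_per_mL": 1 - 155 / 248,
}


class SyntheticCohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_deliveries: int = Field(default=9_471, gt=0)
    live_birth_rate: float = Field(default=9_136 / 9_471, ge=0, le=1)
    p_case: float = Field(default=248 / 9_471, ge=0, le=1)
    p_death_given_case: float = Field(default=32 / 248, ge=0, le=1)
    criterion_prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    severity_loading: float = Field(default=0.6, ge=0, le=1)
    transfusion_distribution: tuple[float, ...] = _DEFAULT_TRANSFUSION_DIST
    sole_transfusion_fraction: float = Field(default=77 / 108, ge=0, le=1)
    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    seed: int = 0

    @field_validator("criterion_prevalence", "missingness_rates")
    @classmethod
    def _probabilities(cls, v):
        for key, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{key!r}: probability {p} outside [0, 1]")
        return v

    @field_validator("transfusion_distribution")
    @classmethod
    def _distribution(cls, v):
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("transfusion_distribution must be a probability vector")
        return v


def _copula_fire(
    rng: np.random.Generator, z: np.ndarray, p: float, loading: float
) -> np.ndarray:
    """Bernoulli(p) marginals correlated with the latent severity z."""
    u = rng.standard_normal(z.shape)
    latent = loading * z + np.sqrt(1.0 - loading**2) * u
    return latent < norm.ppf(p)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[MaternalCaseRecord], CohortDenominators]:
    """Generate the case records of one synthetic delivery cohort.

    Returns the criteria-positive case records plus denominators; the
    remaining ``n_deliveries - len(records)`` deliveries are event-free
    survivors represented only by the denominator, exactly as the audit
    fixtures represent them.
    """
    rng = np.random.default_rng(config.seed)
    registry = builtin_registry()
    unknown = set(config.criterion_prevalence) - set(registry)
    if unknown:
        raise ValueError(f"unknown criteria in prevalence map: {sorted(unknown)}")

    n_live_births = int(rng.binomial(config.n_deliveries, config.live_birth_rate))
    n_cases = int(rng.binomial(config.n_deliveries, config.p_case))
    denominators = CohortDenominators(
        n_deliveries=config.n_deliveries, n_live_births=max(1, n_live_births)
    )

    z = rng.standard_normal(n_cases)
    crit_ids = list(config.criterion_prevalence)
    fired = {
        c: _copula_fire(rng, z, config.criterion_prevalence[c], config.severity_loading)
        for c in crit_ids
    }
    dead = _copula_fire(rng, z, config.p_death_given_case, config.severity_loading)
    units = rng.choice(
        len(config.transfusion_distribution),
        size=n_cases,
        p=np.asarray(config.transfusion_distribution),
    )
    sole_draw = rng.random(n_cases) < config.sole_transfusion_fraction
    # fallback criterion for cases the copula left empty, by highest prevalence
    fallback = max(config.criterion_prevalence, key=config.criterion_prevalence.get)

    records: list[MaternalCaseRecord] = []
    for i in range(n_cases):
        intended = {c for c in crit_ids if fired[c][i]}
        if units[i] == 1:
            # one-unit recipients: a configured fraction has no other criterion
            if sole_draw[i]:
                intended = set()
            elif not intended:
                intended = {fallback}
        if not intended and units[i] == 0:
            intended = {fallback}

        values: dict = {}
        for c in intended:
            apply_recipe(values, c)
        values["blood_units_transfused"] = int(units[i])

        # protected: fields a met criterion needs stay documented
        protected = set()
        for c in intended:
            protected.update(registry[c].required_fields)
        for fld, miss in config.missingness_rates.items():
            if fld in protected:
                continue
            if rng.random() < miss:
                values.pop(fld, None)
            elif fld not in values:
                values[fld] = NORMAL_VALUES[fld]

        records.append(
            MaternalCaseRecord(
                case_id=f"sim-{i:05d}",
                outcome=Outcome.dead if dead[i] else Outcome.alive,
                **values,
            )
        )
    return records, denominators
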
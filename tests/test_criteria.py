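"""Criteria registry, predicate semantics and case classification."""

import pytest

from nearmiss_audit.case_model import MaternalCaseRecord
from nearmiss_audit.criteria import (
    Category,
    ConfigurationError,
    CriteriaProfile,
    WHO_CLINICAL_CRITERION_IDS,
    WHO_CRITERION_IDS,
    classify_case,
    classify_cohort,
    evaluate_criterion,
    load_profile,
)
from nearmiss_audit.simulate import SyntheticCohortConfig, generate_cohort


def _rec(**kwargs):
    kwargs.setdefault("case_id", "x")
    kwargs.setdefault("outcome", "alive")
    return MaternalCaseRecord(**kwargs)


SHOCK_FIELDS = dict(
    sbp_min_sustained_mmHg=80, pulse_max_concurrent_bpm=130, fluids_given_L=2.5
)


class TestRegistry:
    def test_who_profile_fully_resolvable(self, registry, who_profile):
        assert len(who_profile.included_criteria) == 25
        who_profile.validate_against(registry)
        assert set(WHO_CRITERION_IDS) <= set(registry)

    def test_category_counts(self, registry):
        by_cat = {}
        for d in registry.values():
            by_cat.setdefault(d.category, []).append(d.criterion_id)
        assert len(by_cat[Category.clinical]) == 11
        assert len(by_cat[Category.laboratory]) == 8
        assert len(by_cat[Category.management]) == 7  # 6 WHO + ICU admission
        assert len(by_cat[Category.disease]) == 3
        assert registry["shock"].category is Category.clinical

    def test_clinical_ids_are_the_clinical_category(self, registry):
        clinical = {c for c, d in registry.items() if d.category is Category.clinical}
        assert clinical == set(WHO_CLINICAL_CRITERION_IDS)

    def test_every_parameter_has_a_default(self, registry):
        for d in registry.values():
            assert all(isinstance(v, (int, float)) for v in d.parameters.values())


class TestPredicates:
    @pytest.mark.parametrize(
        "cid, fields, met",
        [
            ("shock", SHOCK_FIELDS, True),
            # persistent hypotension but adequate pulse: not shock
            ("shock", {**SHOCK_FIELDS, "pulse_max_concurrent_bpm": 110}, False),
            ("shock", {**SHOCK_FIELDS, "fluids_given_L": 1.0}, False),
            ("resp_rate_extreme", dict(resp_rate_extreme_per_min=44), True),
            ("resp_rate_extreme", dict(resp_rate_extreme_per_min=5), True),
            ("resp_rate_extreme", dict(resp_rate_extreme_per_min=30), False),
            (
                "sepsis",
                dict(
                    clinical_infection_sign=True,
                    temp_extreme_C=39.0,
                    resp_rate_extreme_per_min=24,
                    pulse_max_concurrent_bpm=95,
                    wbc_10e9_per_L=8,
                ),
                True,  # 3 of 4 inflammatory components satisfied
            ),
            (
                "sepsis",
                dict(
                    clinical_infection_sign=True,
                    temp_extreme_C=37.0,
                    resp_rate_extreme_per_min=24,
                    pulse_max_concurrent_bpm=95,
                    wbc_10e9_per_L=8,
                ),
                False,  # only 2 of 4
            ),
            (
                "oliguria",
                dict(
                    urine_output_mL_per_h_4h=20,
                    urine_output_mL_24h=500,
                    oliguria_refractory=True,
                ),
                True,
            ),
            (
                "oliguria",
                dict(
                    urine_output_mL_per_h_4h=20,
                    urine_output_mL_24h=500,
                    oliguria_refractory=False,
                ),
                False,
            ),
            ("loss_of_consciousness", dict(unconscious_hours=14, gcs_min=14), True),
            ("loss_of_consciousness", dict(unconscious_hours=2, gcs_min=8), True),
            ("loss_of_consciousness", dict(unconscious_hours=2, gcs_min=14), False),
            ("eclampsia", dict(hypertension=True, proteinuria=True, fits=True), True),
            ("eclampsia", dict(hypertension=True, proteinuria=False, fits=True), False),
            ("thrombocytopenia", dict(platelets_per_mL=49_000), True),
            ("thrombocytopenia", dict(platelets_per_mL=50_000), False),
            ("clotting_failure", dict(clot_formation_minutes=9), True),
            ("clotting_failure", dict(clot_formation_minutes=5), False),
            ("spo2_low", dict(spo2_min_pct=85, spo2_low_duration_min=60), True),
            ("spo2_low", dict(spo2_min_pct=85, spo2_low_duration_min=30), False),
            (
                "intubation",
                dict(intubation_minutes=90, intubation_anaesthesia_related=False),
                True,
            ),
            (
                "intubation",
                dict(intubation_minutes=90, intubation_anaesthesia_related=True),
                False,
            ),
        ],
    )
    def test_predicate_examples(self, registry, cid, fields, met):
        ev = evaluate_criterion(_rec(**fields), registry[cid])
        assert ev.evaluable
        assert ev.met is met

    def test_transfusion_threshold_parameter(self, registry):
        rec = _rec(blood_units_transfused=4)
        d = registry["transfusion"]
        assert not evaluate_criterion(rec, d).met  # default threshold 5
        assert evaluate_criterion(rec, d, {"transfusion_threshold_units": 1}).met

    @pytest.mark.parametrize("cid", sorted(WHO_CRITERION_IDS))
    def test_all_missing_record_never_fires(self, registry, cid):
        """Missing required fields make any criterion unevaluable, hence unmet."""
        ev = evaluate_criterion(_rec(), registry[cid])
        if cid == "transfusion":  # units default to an affirmative 0
            assert ev.evaluable and not ev.met
        else:
            assert not ev.evaluable and not ev.met

    def test_unknown_parameter_rejected(self, registry):
        with pytest.raises(ConfigurationError, match="bogus"):
            evaluate_criterion(_rec(**SHOCK_FIELDS), registry["shock"], {"bogus": 1})


class TestClassification:
    def test_survivor_meeting_shock_is_mnm(self, registry, haydom_profile):
        c = classify_case(_rec(**SHOCK_FIELDS), haydom_profile, registry)
        assert c.label.value == "MNM"
        assert c.met_criteria == {"shock"}

    def test_death_without_criteria_is_md(self, registry, haydom_profile):
        c = classify_case(_rec(outcome="dead"), haydom_profile, registry)
        assert c.label.value == "MD"
        assert c.met_criteria == frozenset()

    def test_single_unit_transfusion_profiles_disagree(
        self, registry, haydom_profile, who_profile
    ):
        rec = _rec(blood_units_transfused=1)
        assert classify_case(rec, haydom_profile, registry).label.value == "MNM"
        assert classify_case(rec, who_profile, registry).label.value == "non_case"

    def test_empty_cohort(self, registry, haydom_profile):
        _, counts = classify_cohort([], haydom_profile, registry)
        assert counts == {"n_MD": 0, "n_MNM": 0, "n_non_case": 0}

    def test_audit_cohort_counts_both_profiles(
        self, registry, haydom_profile, who_profile, audit_cohort
    ):
        records, _ = audit_cohort
        _, haydom = classify_cohort(records, haydom_profile, registry)
        assert (haydom["n_MD"], haydom["n_MNM"]) == (32, 216)
        _, who = classify_cohort(records, who_profile, registry)
        assert (who["n_MD"], who["n_MNM"]) == (32, 60)

    def test_label_partition_sums_to_cohort_size(self, registry, haydom_profile):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=7, n_deliveries=2000))
        _, counts = classify_cohort(records, haydom_profile, registry)
        assert sum(counts.values()) == len(records)


class TestMonotonicity:
    def test_subset_profile_never_gains_positives(self, registry, audit_cohort):
        """Every case positive under the clinical subset is positive under full WHO."""
        records, _ = audit_cohort
        clinical = load_profile("WHO-clinical")
        full = load_profile("WHO")
        cl_a, _ = classify_cohort(records, clinical, registry)
        cl_b, _ = classify_cohort(records, full, registry)
        for a, b in zip(cl_a, cl_b):
            assert a.met_criteria <= b.met_criteria

    @pytest.mark.parametrize("seed", [0, 1])
    def test_raising_transfusion_threshold_monotone(self, registry, seed):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=seed, n_deliveries=2000))
        positives = []
        for t in (1, 2, 3, 5):
            prof = CriteriaProfile(
                "local",
                ["transfusion", "shock", "icu_admission"],
                {"transfusion": {"transfusion_threshold_units": t}},
            )
            cls, _ = classify_cohort(records, prof, registry)
            positives.append({c.case_id for c in cls if c.met_criteria})
        for tighter, looser in zip(positives[1:], positives):
            assert tighter <= looser

    def test_met_implies_evaluable_everywhere(self, registry, audit_cohort):
        records, _ = audit_cohort
        for rec in records[::10]:
            for d in registry.values():
                ev = evaluate_criterion(rec, d)
                assert ev.evaluable or not ev.met


def test_profile_round_trip_serialization(tmp_path, haydom_profile, registry):
    import yaml

    path = tmp_path / "custom.yaml"
    path.write_text(yaml.safe_dump(haydom_profile.to_dict()))
    loaded = load_profile(path)
    assert loaded.to_dict() == haydom_profile.to_dict()
    loaded.validate_against(registry)


def test_profile_validation_rejects_unknowns(registry):
    with pytest.raises(ConfigurationError):
        load_profile("no-such-profile")
    with pytest.raises(ConfigurationError):
        CriteriaProfile("p", ["not_a_criterion"]).validate_against(registry)
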
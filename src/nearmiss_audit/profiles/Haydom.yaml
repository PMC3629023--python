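# WHO maternal near-miss criteria adapted to the local context of Haydom
# Lutheran Hospital: all 11 clinical criteria; the two measurable laboratory
# criteria; five management criteria with the transfusion threshold lowered
# to one unit (no blood bank) and ICU admission added; plus the disease-based
# criteria eclampsia, sepsis and uterine rupture.
profile_name: Haydom
included_criteria:
  - acute_cyanosis
  - gasping
  - resp_rate_extreme
  - shock
  - oliguria
  - clotting_failure
  - loss_of_consciousness
  - cardiac_arrest
  - stroke
  - uncontrollable_fit
  - jaundice_preeclampsia
  - spo2_low
  - thrombocytopenia
  - icu_admission
  - hysterectomy
  - transfusion
  - intubation
  - cpr
  - eclampsia
  - sepsis
  - uterine_rupture
parameter_overrides:
  transfusion:
    transfusion_threshold_units: 1
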
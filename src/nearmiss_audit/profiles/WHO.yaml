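# Full WHO maternal near-miss inclusion criteria (25 criteria:
# 11 clinical, 8 laboratory-based, 6 management-based).
profile_name: WHO
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
  - pao2_fio2_low
  - creatinine_high
  - bilirubin_high
  - ph_low
  - lactate_high
  - thrombocytopenia
  - unconscious_ketoacids
  - vasoactive_drugs
  - hysterectomy
  - transfusion
  - intubation
  - dialysis
  - cpr
parameter_overrides:
  transfusion:
    transfusion_threshold_units: 5
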
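# The 11 clinical WHO maternal near-miss inclusion criteria only.
profile_name: WHO-clinical
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
parameter_overrides: {}
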
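# Outcome definitions: named concept sets, composites, negative-control flags.
# TTS variants are configured separately (tts_definitions in the study file)
# because they combine a thrombosis outcome with platelet/diagnosis evidence.
- name: deep_vein_thrombosis
  concepts: [deep_vein_thrombosis]
- name: pulmonary_embolism
  concepts: [pulmonary_embolism]
- name: ischaemic_stroke
  concepts: [ischaemic_stroke]
- name: myocardial_infarction
  concepts: [myocardial_infarction]
- name: thrombocytopenia
  concepts: [thrombocytopenia]
- name: venous_thromboembolism
  composite_of: [deep_vein_thrombosis, pulmonary_embolism]
- name: arterial_thromboembolism
  composite_of: [ischaemic_stroke, myocardial_infarction]
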
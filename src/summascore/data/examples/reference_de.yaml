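# Reference bundle for a German tuberculosis virtual patient.
vp_id: vp-tb-de
language: de
expert_statement: >-
  Anna Müller stellt sich mit chronischem Husten, Gewichtsverlust,
  Appetitlosigkeit, Nachtschweiß und Hämoptyse vor; Verdacht auf
  Tuberkulose.
patient_name: Anna Müller
final_diagnoses:
  - Tuberkulose
key_findings:
  - Husten
  - Nachtschweiß
  - Hämoptyse
  - Gewichtsverlust
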
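# Reference bundle for an English tuberculosis virtual patient.
vp_id: vp-tb-en
language: en
expert_statement: >-
  Anna Miller presents with chronic cough, weight loss, loss of appetite,
  night sweats and hemoptysis; tuberculosis is suspected.
patient_name: Anna Miller
final_diagnoses:
  - tuberculosis
key_findings:
  - cough
  - night sweats
  - hemoptysis
  - weight loss
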
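# Categorized medical thesaurus, English: form, category, language.
# A curated subset in the spirit of an adapted MeSH vocabulary; the format
# also accepts bulk imports from MeSH descriptor exports.
cough	finding	en
smoking	finding	en
weight loss	finding	en
loss of appetite	finding	en
night sweats	finding	en
hemoptysis	finding	en
fever	finding	en
fatigue	finding	en
dyspnea	finding	en
chest pain	finding	en
abdominal pain	finding	en
nausea	finding	en
vomiting	finding	en
diarrhea	finding	en
headache	finding	en
wheezing	finding	en
jaundice	finding	en
edema	finding	en
rash	finding	en
sputum	anatomical	en
lung	anatomical	en
chest	anatomical	en
abdomen	anatomical	en
throat	anatomical	en
liver	anatomical	en
heart	anatomical	en
colon	anatomical	en
hypertension	diagnosis	en
tuberculosis	diagnosis	en
asthma	diagnosis	en
pneumonia	diagnosis	en
bronchitis	diagnosis	en
diabetes	diagnosis	en
ulcerative colitis	diagnosis	en
appendicitis	diagnosis	en
anemia	diagnosis	en
china	place	en
germany	place	en
spain	place	en
india	place	en
munich	place	en
berlin	place	en
london	place	en
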
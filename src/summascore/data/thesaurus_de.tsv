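# Categorized medical thesaurus, German: form, category, language.
husten	finding	de
rauchen	finding	de
gewichtsverlust	finding	de
appetitlosigkeit	finding	de
nachtschweiß	finding	de
hämoptyse	finding	de
fieber	finding	de
müdigkeit	finding	de
atemnot	finding	de
brustschmerz	finding	de
bauchschmerz	finding	de
übelkeit	finding	de
erbrechen	finding	de
durchfall	finding	de
kopfschmerz	finding	de
auswurf	anatomical	de
lunge	anatomical	de
brustkorb	anatomical	de
abdomen	anatomical	de
leber	anatomical	de
herz	anatomical	de
hypertonie	diagnosis	de
tuberkulose	diagnosis	de
asthma	diagnosis	de
pneumonie	diagnosis	de
bronchitis	diagnosis	de
diabetes	diagnosis	de
colitis ulcerosa	diagnosis	de
appendizitis	diagnosis	de
anämie	diagnosis	de
china	place	de
deutschland	place	de
münchen	place	de
berlin	place	de
spanien	place	de
indien	place	de
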
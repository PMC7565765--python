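# Semantic qualifiers, German: form, language, match_mode, antonym.
# Prefix-mode entries are shared with English via sq_en.tsv (language
# 'both') when both files are loaded; they are repeated here so a
# German-only load still catches them.
akut	de	lemma-exact	chronisch
chronisch	de	lemma-exact	akut
mild	de	lemma-exact	schwer
schwer	de	lemma-exact	mild
einseitig	de	lemma-exact	beidseitig
beidseitig	de	lemma-exact	einseitig
plötzlich	de	lemma-exact	allmählich
allmählich	de	lemma-exact	plötzlich
konstant	de	lemma-exact	intermittierend
intermittierend	de	lemma-exact	konstant
scharf	de	lemma-exact	dumpf
dumpf	de	lemma-exact	scharf
lokalisiert	de	lemma-exact	diffus
diffus	de	lemma-exact	lokalisiert
proximal	de	lemma-exact	distal
distal	de	lemma-exact	proximal
schmerzhaft	de	lemma-exact	schmerzlos
schmerzlos	de	lemma-exact	schmerzhaft
produktiv	de	lemma-exact	unproduktiv
unproduktiv	de	lemma-exact	produktiv
hyper	both	token-prefix	hypo
hypo	both	token-prefix	hyper
tachy	both	token-prefix	brady
brady	both	token-prefix	tachy
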
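# Semantic qualifiers, English: form, language, match_mode, antonym.
# Paired qualitative descriptors used in clinical reasoning, after the
# widely used qualifier list tradition; prefix-mode entries catch
# qualifiers embedded in longer tokens (hyper in hypertension).
acute	en	lemma-exact	chronic
chronic	en	lemma-exact	acute
mild	en	lemma-exact	severe
severe	en	lemma-exact	mild
unilateral	en	lemma-exact	bilateral
bilateral	en	lemma-exact	unilateral
left-sided	en	lemma-exact	right-sided
right-sided	en	lemma-exact	left-sided
sudden	en	lemma-exact	gradual
gradual	en	lemma-exact	sudden
constant	en	lemma-exact	intermittent
intermittent	en	lemma-exact	constant
sharp	en	lemma-exact	dull
dull	en	lemma-exact	sharp
localized	en	lemma-exact	diffuse
diffuse	en	lemma-exact	localized
proximal	en	lemma-exact	distal
distal	en	lemma-exact	proximal
painful	en	lemma-exact	painless
painless	en	lemma-exact	painful
productive	en	lemma-exact	nonproductive
nonproductive	en	lemma-exact	productive
hyper	both	token-prefix	hypo
hypo	both	token-prefix	hyper
tachy	both	token-prefix	brady
brady	both	token-prefix	tachy
macro	both	token-prefix	micro
micro	both	token-prefix	macro
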
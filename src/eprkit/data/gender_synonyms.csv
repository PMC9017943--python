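text,gender
f,F
female,F
femme,F
feminin,F
m,M
male,M
homme,M
masculin,M
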
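inn
rituximab
bortezomib
azacitidine
imatinib
oxaliplatin
irinotecan
cetuximab
panitumumab
trabectedin
daratumumab
cytarabine
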
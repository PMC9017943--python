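text,stage
early,early
precoce,early
stade precoce,early
localized,early
localise,early
adjuvant,early
neoadjuvant,early
locally advanced,locally_advanced
locally_advanced,locally_advanced
localement avance,locally_advanced
stade iii,locally_advanced
metastatic,metastatic
metastatique,metastatic
metastase,metastatic
stade iv,metastatic
m+,metastatic
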
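keyword,stage
metastatic,metastatic
metastatique,metastatic
palliative,metastatic
palliatif,metastatic
locally advanced,locally_advanced
localement avance,locally_advanced
neoadjuvant,early
adjuvant,early
curative,early
curatif,early
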
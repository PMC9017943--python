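alias,inn
trastuzumab emtansin,trastuzumab emtansine
trastuzumab-emtansine,trastuzumab emtansine
t-dm1,trastuzumab emtansine
tdm1,trastuzumab emtansine
5-fu,fluorouracil
5fu,fluorouracil
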
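brand,inn
Herceptin,trastuzumab
Kadcyla,trastuzumab emtansine
Perjeta,pertuzumab
Avastin,bevacizumab
Tecentriq,atezolizumab
Taxol,paclitaxel
Taxotere,docetaxel
Paraplatine,carboplatin
Cisplatyl,cisplatin
Alimta,pemetrexed
Navelbine,vinorelbine
Gemzar,gemcitabine
Adriblastine,doxorubicin
Endoxan,cyclophosphamide
Xeloda,capecitabine
Halaven,eribulin
Mabthera,rituximab
Velcade,bortezomib
Vidaza,azacitidine
Glivec,imatinib
Eloxatine,oxaliplatin
Campto,irinotecan
Erbitux,cetuximab
Vectibix,panitumumab
Yondelis,trabectedin
Darzalex,daratumumab
Aracytine,cytarabine
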
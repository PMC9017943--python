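text,response
cr,CR
complete response,CR
reponse complete,CR
pr,PR
partial response,PR
reponse partielle,PR
sd,SD
stable disease,SD
stabilite,SD
pd,PD
progression,PD
progressive disease,PD
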
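acronym,expansion
6mwt,six-minute walking test
bi,brain injury
adl,activities of daily living
iadl,instrumental activities of daily living
tug,timed up and go
rom,range of motion
10mwt,ten-meter walking test
bbs,berg balance scale
fim,functional independence measure
qol,quality of life
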
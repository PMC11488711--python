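species,algerianus,bernardi,kraussei,microcellatus,ravouxi,stumperi
algerianus,41,0,1,1,2,0
bernardi,1,9,1,0,0,0
kraussei,1,0,58,0,1,0
microcellatus,0,0,0,39,1,0
ravouxi,2,2,0,0,156,0
stumperi,0,0,0,0,1,32
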
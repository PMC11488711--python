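species,adlerzi,algerianus,bernardi,birgitae,corsicus,kraussei,microcellatus,ravouxi,stumperi
adlerzi,13,0,0,0,0,0,0,3,0
algerianus,0,31,0,0,0,1,0,0,0
bernardi,0,0,7,0,0,0,0,0,0
birgitae,0,0,0,8,0,0,0,0,0
corsicus,0,1,0,0,74,1,0,0,0
kraussei,0,0,0,0,0,90,0,1,0
microcellatus,0,0,0,0,0,0,30,0,0
ravouxi,2,2,0,0,0,0,0,98,0
stumperi,0,0,0,0,0,0,0,0,18
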
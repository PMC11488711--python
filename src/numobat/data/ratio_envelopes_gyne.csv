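species,n,row,mean,sd
adlerzi,17,CS,621,21.665
adlerzi,17,CL/CWb,1.181,0.014
adlerzi,17,POC/CL,0.364,0.009
adlerzi,17,SL/CL,0.650,0.029
adlerzi,17,FR/CS,0.330,0.011
adlerzi,17,MW/CS,0.864,0.027
adlerzi,17,SPWI/CS,0.383,0.017
adlerzi,17,SPTI/CS,0.337,0.017
adlerzi,17,PEW/CS,0.309,0.013
adlerzi,17,PPW/CS,0.448,0.014
adlerzi,17,ML/CS,1.452,0.038
adlerzi,17,SPST/CS,0.284,0.010
adlerzi,17,PLST/CS,0.395,0.010
adlerzi,17,PEH/CS,0.622,0.012
adlerzi,17,SPH/CS,0.288,0.019
adlerzi,17,PPH/CS,0.491,0.009
adlerzi,17,EYE/CS,0.296,0.009
algerianus,34,CS,615,18.398
algerianus,34,CL/CWb,1.184,0.019
algerianus,34,POC/CL,0.373,0.007
algerianus,34,SL/CL,0.681,0.014
algerianus,34,FR/CS,0.357,0.013
algerianus,34,MW/CS,0.842,0.029
algerianus,34,SPWI/CS,0.407,0.015
algerianus,34,SPTI/CS,0.368,0.010
algerianus,34,PEW/CS,0.299,0.014
algerianus,34,PPW/CS,0.427,0.017
algerianus,34,ML/CS,1.458,0.034
algerianus,34,SPST/CS,0.250,0.013
algerianus,34,PLST/CS,0.396,0.011
algerianus,34,PEH/CS,0.583,0.017
algerianus,34,SPH/CS,0.255,0.018
algerianus,34,PPH/CS,0.479,0.020
algerianus,34,EYE/CS,0.274,0.007
bernardi,7,CS,589,10.618
bernardi,7,CL/CWb,1.186,0.013
bernardi,7,POC/CL,0.348,0.005
bernardi,7,SL/CL,0.694,0.012
bernardi,7,FR/CS,0.366,0.007
bernardi,7,MW/CS,0.878,0.033
bernardi,7,SPWI/CS,0.455,0.010
bernardi,7,SPTI/CS,0.413,0.007
bernardi,7,PEW/CS,0.319,0.012
bernardi,7,PPW/CS,0.496,0.012
bernardi,7,ML/CS,1.489,0.014
bernardi,7,SPST/CS,0.247,0.009
bernardi,7,PLST/CS,0.396,0.010
bernardi,7,PEH/CS,0.630,0.012
bernardi,7,SPH/CS,0.295,0.009
bernardi,7,PPH/CS,0.514,0.012
bernardi,7,EYE/CS,0.299,0.005
birgitae,8,CS,589,24.456
birgitae,8,CL/CWb,1.161,0.020
birgitae,8,POC/CL,0.376,0.014
birgitae,8,SL/CL,0.718,0.013
birgitae,8,FR/CS,0.341,0.016
birgitae,8,MW/CS,0.820,0.026
birgitae,8,SPWI/CS,0.406,0.020
birgitae,8,SPTI/CS,0.363,0.019
birgitae,8,PEW/CS,0.312,0.010
birgitae,8,PPW/CS,0.462,0.011
birgitae,8,ML/CS,1.445,0.029
birgitae,8,SPST/CS,0.263,0.009
birgitae,8,PLST/CS,0.405,0.014
birgitae,8,PEH/CS,0.591,0.014
birgitae,8,SPH/CS,0.296,0.019
birgitae,8,PPH/CS,0.485,0.015
birgitae,8,EYE/CS,0.274,0.014
corsicus,92,CS,593,18.745
corsicus,92,CL/CWb,1.207,0.024
corsicus,92,POC/CL,0.356,0.012
corsicus,92,SL/CL,0.625,0.017
corsicus,92,FR/CS,0.364,0.009
corsicus,92,MW/CS,0.796,0.038
corsicus,92,SPWI/CS,0.406,0.019
corsicus,92,SPTI/CS,0.366,0.024
corsicus,92,PEW/CS,0.312,0.013
corsicus,92,PPW/CS,0.469,0.018
corsicus,92,ML/CS,1.379,0.040
corsicus,92,SPST/CS,0.250,0.013
corsicus,92,PLST/CS,0.385,0.016
corsicus,92,PEH/CS,0.601,0.023
corsicus,92,SPH/CS,0.278,0.018
corsicus,92,PPH/CS,0.484,0.015
corsicus,92,EYE/CS,0.265,0.009
kraussei,124,CS,624,21.793
kraussei,124,CL/CWb,1.213,0.024
kraussei,124,POC/CL,0.353,0.008
kraussei,124,SL/CL,0.687,0.019
kraussei,124,FR/CS,0.336,0.010
kraussei,124,MW/CS,0.809,0.028
kraussei,124,SPWI/CS,0.389,0.020
kraussei,124,SPTI/CS,0.359,0.019
kraussei,124,PEW/CS,0.281,0.018
kraussei,124,PPW/CS,0.432,0.019
kraussei,124,ML/CS,1.421,0.039
kraussei,124,SPST/CS,0.251,0.013
kraussei,124,PLST/CS,0.393,0.015
kraussei,124,PEH/CS,0.570,0.020
kraussei,124,SPH/CS,0.277,0.016
kraussei,124,PPH/CS,0.458,0.017
kraussei,124,EYE/CS,0.271,0.009
microcellatus,50,CS,605,15.596
microcellatus,50,CL/CWb,1.127,0.021
microcellatus,50,POC/CL,0.365,0.009
microcellatus,50,SL/CL,0.714,0.019
microcellatus,50,FR/CS,0.353,0.009
microcellatus,50,MW/CS,0.853,0.042
microcellatus,50,SPWI/CS,0.378,0.015
microcellatus,50,SPTI/CS,0.325,0.013
microcellatus,50,PEW/CS,0.285,0.013
microcellatus,50,PPW/CS,0.445,0.020
microcellatus,50,ML/CS,1.473,0.036
microcellatus,50,SPST/CS,0.249,0.009
microcellatus,50,PLST/CS,0.418,0.015
microcellatus,50,PEH/CS,0.582,0.019
microcellatus,50,SPH/CS,0.328,0.028
microcellatus,50,PPH/CS,0.433,0.019
microcellatus,50,EYE/CS,0.313,0.009
ravouxi,121,CS,635,20.777
ravouxi,121,CL/CWb,1.181,0.025
ravouxi,121,POC/CL,0.362,0.011
ravouxi,121,SL/CL,0.651,0.017
ravouxi,121,FR/CS,0.357,0.015
ravouxi,121,MW/CS,0.890,0.030
ravouxi,121,SPWI/CS,0.410,0.020
ravouxi,121,SPTI/CS,0.368,0.018
ravouxi,121,PEW/CS,0.304,0.016
ravouxi,121,PPW/CS,0.452,0.017
ravouxi,121,ML/CS,1.517,0.034
ravouxi,121,SPST/CS,0.266,0.013
ravouxi,121,PLST/CS,0.400,0.020
ravouxi,121,PEH/CS,0.620,0.026
ravouxi,121,SPH/CS,0.293,0.020
ravouxi,121,PPH/CS,0.484,0.022
ravouxi,121,EYE/CS,0.292,0.009
stumperi,20,CS,583,8.563
stumperi,20,CL/CWb,1.097,0.024
stumperi,20,POC/CL,0.363,0.009
stumperi,20,SL/CL,0.718,0.019
stumperi,20,FR/CS,0.343,0.012
stumperi,20,MW/CS,0.850,0.037
stumperi,20,SPWI/CS,0.316,0.013
stumperi,20,SPTI/CS,0.269,0.014
stumperi,20,PEW/CS,0.273,0.009
stumperi,20,PPW/CS,0.418,0.013
stumperi,20,ML/CS,1.444,0.166
stumperi,20,SPST/CS,0.263,0.006
stumperi,20,PLST/CS,0.393,0.010
stumperi,20,PEH/CS,0.588,0.018
stumperi,20,SPH/CS,0.279,0.019
stumperi,20,PPH/CS,0.449,0.018
stumperi,20,EYE/CS,0.291,0.008
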
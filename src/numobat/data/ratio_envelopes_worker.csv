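species,n,row,mean,sd
algerianus,44,CS,598,21.265
algerianus,44,CL/CWb,1.232,0.019
algerianus,44,POC/CL,0.372,0.010
algerianus,44,SL/CL,0.702,0.015
algerianus,44,FR/CS,0.356,0.013
algerianus,44,MW/CS,0.661,0.021
algerianus,44,SPBA/CS,0.355,0.013
algerianus,44,SPWI/CS,0.367,0.016
algerianus,44,SPTI/CS,0.349,0.017
algerianus,44,PEW/CS,0.295,0.015
algerianus,44,PPW/CS,0.423,0.020
algerianus,44,ML/CS,1.232,0.030
algerianus,44,SPST/CS,0.225,0.013
algerianus,44,PLST/CS,0.362,0.013
algerianus,44,PEH/CS,0.574,0.019
algerianus,44,SPH/CS,0.268,0.013
algerianus,44,PPH/CS,0.468,0.014
algerianus,44,EYE/CS,0.244,0.008
bernardi,10,CS,564,15.214
bernardi,10,CL/CWb,1.243,0.023
bernardi,10,POC/CL,0.368,0.017
bernardi,10,SL/CL,0.714,0.031
bernardi,10,FR/CS,0.362,0.009
bernardi,10,MW/CS,0.684,0.021
bernardi,10,SPBA/CS,0.348,0.018
bernardi,10,SPWI/CS,0.387,0.015
bernardi,10,SPTI/CS,0.360,0.017
bernardi,10,PEW/CS,0.328,0.025
bernardi,10,PPW/CS,0.497,0.016
bernardi,10,ML/CS,1.252,0.033
bernardi,10,SPST/CS,0.239,0.013
bernardi,10,PLST/CS,0.367,0.021
bernardi,10,PEH/CS,0.609,0.028
bernardi,10,SPH/CS,0.295,0.019
bernardi,10,PPH/CS,0.500,0.027
bernardi,10,EYE/CS,0.258,0.021
gordiagini,1,CS,579,
gordiagini,1,CL/CWb,1.162,
gordiagini,1,POC/CL,0.372,
gordiagini,1,SL/CL,0.723,
gordiagini,1,FR/CS,0.420,
gordiagini,1,MW/CS,0.695,
gordiagini,1,SPBA/CS,0.302,
gordiagini,1,SPWI/CS,0.290,
gordiagini,1,SPTI/CS,0.258,
gordiagini,1,PEW/CS,0.291,
gordiagini,1,PPW/CS,0.442,
gordiagini,1,ML/CS,1.292,
gordiagini,1,SPST/CS,0.280,
gordiagini,1,PLST/CS,0.411,
gordiagini,1,PEH/CS,0.560,
gordiagini,1,SPH/CS,0.280,
gordiagini,1,PPH/CS,0.458,
gordiagini,1,EYE/CS,0.265,
kraussei,70,CS,599,19.488
kraussei,70,CL/CWb,1.268,0.022
kraussei,70,POC/CL,0.354,0.009
kraussei,70,SL/CL,0.706,0.018
kraussei,70,FR/CS,0.337,0.009
kraussei,70,MW/CS,0.623,0.016
kraussei,70,SPBA/CS,0.348,0.017
kraussei,70,SPWI/CS,0.381,0.025
kraussei,70,SPTI/CS,0.365,0.024
kraussei,70,PEW/CS,0.285,0.018
kraussei,70,PPW/CS,0.437,0.020
kraussei,70,ML/CS,1.210,0.034
kraussei,70,SPST/CS,0.256,0.018
kraussei,70,PLST/CS,0.355,0.019
kraussei,70,PEH/CS,0.571,0.025
kraussei,70,SPH/CS,0.285,0.016
kraussei,70,PPH/CS,0.465,0.018
kraussei,70,EYE/CS,0.236,0.008
microcellatus,51,CS,590,20.033
microcellatus,51,CL/CWb,1.192,0.020
microcellatus,51,POC/CL,0.369,0.019
microcellatus,51,SL/CL,0.734,0.018
microcellatus,51,FR/CS,0.361,0.008
microcellatus,51,MW/CS,0.663,0.012
microcellatus,51,SPBA/CS,0.312,0.016
microcellatus,51,SPWI/CS,0.328,0.015
microcellatus,51,SPTI/CS,0.308,0.016
microcellatus,51,PEW/CS,0.287,0.012
microcellatus,51,PPW/CS,0.438,0.016
microcellatus,51,ML/CS,1.251,0.026
microcellatus,51,SPST/CS,0.227,0.014
microcellatus,51,PLST/CS,0.392,0.015
microcellatus,51,PEH/CS,0.570,0.017
microcellatus,51,SPH/CS,0.317,0.029
microcellatus,51,PPH/CS,0.419,0.014
microcellatus,51,EYE/CS,0.258,0.010
ravouxi,174,CS,614,26.021
ravouxi,174,CL/CWb,1.232,0.027
ravouxi,174,POC/CL,0.368,0.010
ravouxi,174,SL/CL,0.672,0.022
ravouxi,174,FR/CS,0.362,0.014
ravouxi,174,MW/CS,0.672,0.022
ravouxi,174,SPBA/CS,0.356,0.021
ravouxi,174,SPWI/CS,0.378,0.026
ravouxi,174,SPTI/CS,0.357,0.027
ravouxi,174,PEW/CS,0.313,0.017
ravouxi,174,PPW/CS,0.456,0.021
ravouxi,174,ML/CS,1.274,0.037
ravouxi,174,SPST/CS,0.262,0.021
ravouxi,174,PLST/CS,0.376,0.019
ravouxi,174,PEH/CS,0.621,0.031
ravouxi,174,SPH/CS,0.306,0.021
ravouxi,174,PPH/CS,0.487,0.021
ravouxi,174,EYE/CS,0.250,0.009
stumperi,35,CS,582,16.108
stumperi,35,CL/CWb,1.143,0.020
stumperi,35,POC/CL,0.358,0.013
stumperi,35,SL/CL,0.703,0.030
stumperi,35,FR/CS,0.336,0.012
stumperi,35,MW/CS,0.706,0.017
stumperi,35,SPBA/CS,0.314,0.015
stumperi,35,SPWI/CS,0.332,0.021
stumperi,35,SPTI/CS,0.303,0.020
stumperi,35,PEW/CS,0.279,0.009
stumperi,35,PPW/CS,0.438,0.014
stumperi,35,ML/CS,1.273,0.022
stumperi,35,SPST/CS,0.244,0.014
stumperi,35,PLST/CS,0.372,0.015
stumperi,35,PEH/CS,0.594,0.015
stumperi,35,SPH/CS,0.291,0.017
stumperi,35,PPH/CS,0.465,0.015
stumperi,35,EYE/CS,0.253,0.010
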
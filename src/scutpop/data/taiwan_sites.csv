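species,population,latitude,longitude,altitude,bio2,bio8,bio9,bio13,bio18,bio19
S. barbata,YH,25.00708,121.5280,15,6.04,27.73,17.58,300,782,376
S. barbata,CL,24.97636,121.9265,257,5.77,22.07,16.90,452,833,666
S. barbata,YL,24.74310,121.7679,5,5.98,23.47,18.53,429,742,469
S. barbata,TC,24.84704,121.7965,71,5.90,23.10,17.97,430,879,569
S. barbata,XH,23.02808,120.3320,21,8.58,27.83,20.17,483,1284,65
S. barbata,WL,24.86637,121.5498,474,6.18,23.27,14.12,452,1179,495
S. taipeiensis,MK,24.97265,121.5962,281,6.01,24.37,16.60,427,1101,598
S. taipeiensis,DA,25.01841,121.5417,337,6.01,27.48,17.42,346,905,503
S. taipeiensis,EG,24.95750,121.6390,49,6.03,24.02,16.47,479,1160,595
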
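study,arm,n,mean_base,sd_base,mean_final,sd_final,corr
ATMH,treated,780,152.28,15.25,132.85,16.72,0.265
ATMH,control,750,153.05,15.73,139.75,17.85,0.284
HEP,treated,150,189.94,16.15,165.06,20.03,0.335
HEP,control,199,191.55,17.64,179.89,22.15,0.331
EWPHE,treated,90,177.33,15.85,156.88,21.26,0.462
EWPHE,control,82,178.23,15.06,170.45,26.91,0.534
HDFP,treated,2427,151.68,19.83,130.09,19.25,0.337
HDFP,control,2370,151.00,19.53,138.54,21.26,0.408
MRC-1,treated,3546,156.60,16.09,135.49,16.32,0.346
MRC-1,control,3445,156.65,15.96,144.25,17.58,0.416
MRC-2,treated,1314,182.19,12.63,153.99,20.13,0.178
MRC-2,control,1337,182.13,12.73,164.58,19.71,0.137
SHEP,treated,2365,170.49,9.5,145.10,19.05,0.315
SHEP,control,2371,170.12,9.24,156.24,20.12,0.253
STOP,treated,137,194.68,12.21,171.46,19.29,0.177
STOP,control,131,194.15,11.16,189.11,21.9,0.414
Sy-Chi,treated,1252,170.73,10.9,150.2,15.84,0.199
Sy-Chi,control,1139,170.25,11.41,156.55,16.86,0.347
Sy-Eur,treated,2398,173.75,9.86,154.87,16.31,0.319
Sy-Eur,control,2297,173.94,10.07,165.24,16.33,0.431
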
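region,hc_n,hc_mean,hc_sd,ibs_n,ibs_mean,ibs_sd
Left Cerebellum WM,19,0.00992,0.00113,20,0.00971,0.00107
Left Cerebellum Cortex,19,0.03628,0.00302,20,0.03553,0.00256
Left Thalamus,19,0.00511,0.00037,20,0.00500,0.00024
Left Caudate,19,0.00239,0.00025,20,0.00228,0.00021
Left Putamen,19,0.00336,0.00033,20,0.00324,0.00028
Left Pallidum,19,0.00140,0.00012,20,0.00135,0.00010
Left Hippocampus,19,0.00270,0.00021,20,0.00272,0.00020
Left Amygdala,19,0.00118,0.00013,20,0.00113,0.00015
Left Accumbens Area,19,0.00031,0.00005,20,0.00034,0.00006
CSF,19,0.00061,0.00009,20,0.00060,0.00012
Right Cerebellum WM,19,0.00908,0.00106,20,0.00922,0.00100
Right Cerebellum Cortex,19,0.03652,0.00321,20,0.03616,0.00264
Right Thalamus,19,0.00488,0.00030,20,0.00475,0.00024
Right Caudate,19,0.00244,0.00024,20,0.00236,0.00024
Right Putamen,19,0.00336,0.00030,20,0.00330,0.00028
Right Pallidum,19,0.00136,0.00012,20,0.00133,0.00010
Right Hippocampus,19,0.00282,0.00022,20,0.00285,0.00021
Right Amygdala,19,0.00125,0.00012,20,0.00120,0.00012
Right Accumbens Area,19,0.00034,0.00004,20,0.00036,0.00005
WM Hypointensities,19,0.00047,0.00015,20,0.00048,0.00013
CC Posterior,19,0.00065,0.00013,20,0.00065,0.00010
CC Mid Posterior,19,0.00038,0.00007,20,0.00036,0.00007
CC Central,19,0.00039,0.00009,20,0.00043,0.00008
CC Mid Anterior,19,0.00041,0.00009,20,0.00044,0.00013
CC Anterior,19,0.00062,0.00010,20,0.00061,0.00008
BrainSegVol,19,0.75340,0.01784,20,0.74913,0.01647
BrainSegVolNotVent,19,0.74137,0.01880,20,0.73857,0.01836
lhCortexVol,19,0.15339,0.00620,20,0.15313,0.00871
rhCortexVol,19,0.15490,0.00690,20,0.15467,0.00859
CortexVol,19,0.30829,0.01298,20,0.30780,0.01715
lhCerebralWhiteMatterVol,19,0.15101,0.00748,20,0.15058,0.00742
rhCerebralWhiteMatterVol,19,0.15103,0.00757,20,0.15075,0.00727
CerebralWhiteMatterVol,19,0.30205,0.01500,20,0.30133,0.01461
SubCortGrayVol,19,0.03930,0.00194,20,0.03855,0.00162
TotalGrayVol,19,0.42105,0.01376,20,0.41884,0.01868
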
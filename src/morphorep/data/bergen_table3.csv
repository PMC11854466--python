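region,hc_n,hc_mean,hc_sd,ibs_n,ibs_mean,ibs_sd
Left Cerebellum WM,29,0.01050,0.00092,49,0.01048,0.00092
Left Cerebellum Cortex,29,0.03894,0.00344,49,0.03931,0.00373
Left Thalamus,29,0.00523,0.00046,49,0.00514,0.00039
Left Caudate,29,0.00236,0.00026,49,0.00236,0.00031
Left Putamen,29,0.00348,0.00038,49,0.00344,0.00039
Left Pallidum,29,0.00140,0.00015,49,0.00137,0.00011
Left Hippocampus,29,0.00291,0.00027,49,0.00290,0.00024
Left Amygdala,29,0.00122,0.00010,49,0.00120,0.00010
Left Accumbens Area,29,0.00043,0.00007,49,0.00042,0.00006
CSF,29,0.00067,0.00012,49,0.00070,0.00014
Right Cerebellum WM,29,0.00997,0.00089,49,0.00998,0.00085
Right Cerebellum Cortex,29,0.03972,0.00344,49,0.03998,0.00376
Right Thalamus,29,0.00512,0.00044,49,0.00507,0.00036
Right Caudate,29,0.00244,0.00024,49,0.00244,0.00030
Right Putamen,29,0.00351,0.00037,49,0.00349,0.00035
Right Pallidum,29,0.00132,0.00013,49,0.00130,0.00011
Right Hippocampus,29,0.00301,0.00024,49,0.00298,0.00023
Right Amygdala,29,0.00128,0.00009,49,0.00127,0.00010
Right Accumbens Area,29,0.00043,0.00005,49,0.00043,0.00006
WM Hypointensities,29,0.00079,0.00031,49,0.00069,0.00025
CC Posterior,29,0.00065,0.00010,49,0.00070,0.00011
CC Mid Posterior,29,0.00037,0.00007,49,0.00040,0.00007
CC Central,29,0.00039,0.00009,49,0.00039,0.00010
CC Mid Anterior,29,0.00038,0.00008,49,0.00041,0.00011
CC Anterior,29,0.00062,0.00010,49,0.00065,0.00010
BrainSegVol,29,0.80464,0.02487,49,0.80558,0.02397
BrainSegVolNotVent,29,0.79224,0.02511,49,0.79132,0.02490
lhCortexVol,29,0.16670,0.00800,49,0.16693,0.00951
rhCortexVol,29,0.16614,0.00828,49,0.16646,0.00939
CortexVol,29,0.33283,0.01611,49,0.33339,0.01880
lhCerebralWhiteMatterVol,29,0.15990,0.00858,49,0.15915,0.00876
rhCerebralWhiteMatterVol,29,0.15925,0.00829,49,0.15827,0.00938
CerebralWhiteMatterVol,29,0.31915,0.01678,49,0.31742,0.01808
SubCortGrayVol,29,0.04092,0.00258,49,0.04063,0.00236
TotalGrayVol,29,0.45307,0.02208,49,0.45396,0.02432
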
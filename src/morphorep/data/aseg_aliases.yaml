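# Mapping from FreeSurfer aseg StructName / header-measure spellings to the
# canonical region labels used throughout this package (summary-table row names).
# Structure rows (whitespace table, StructName column):
Left-Cerebellum-White-Matter: Left Cerebellum WM
Left-Cerebellum-Cortex: Left Cerebellum Cortex
Left-Thalamus-Proper: Left Thalamus
Left-Thalamus: Left Thalamus
Left-Caudate: Left Caudate
Left-Putamen: Left Putamen
Left-Pallidum: Left Pallidum
Left-Hippocampus: Left Hippocampus
Left-Amygdala: Left Amygdala
Left-Accumbens-area: Left Accumbens Area
CSF: CSF
Right-Cerebellum-White-Matter: Right Cerebellum WM
Right-Cerebellum-Cortex: Right Cerebellum Cortex
Right-Thalamus-Proper: Right Thalamus
Right-Thalamus: Right Thalamus
Right-Caudate: Right Caudate
Right-Putamen: Right Putamen
Right-Pallidum: Right Pallidum
Right-Hippocampus: Right Hippocampus
Right-Amygdala: Right Amygdala
Right-Accumbens-area: Right Accumbens Area
WM-hypointensities: WM Hypointensities
CC_Posterior: CC Posterior
CC_Mid_Posterior: CC Mid Posterior
CC_Central: CC Central
CC_Mid_Anterior: CC Mid Anterior
CC_Anterior: CC Anterior
# Header measures (`# Measure` lines) already match the canonical spellings:
BrainSegVol: BrainSegVol
BrainSegVolNotVent: BrainSegVolNotVent
lhCortexVol: lhCortexVol
rhCortexVol: rhCortexVol
CortexVol: CortexVol
lhCerebralWhiteMatterVol: lhCerebralWhiteMatterVol
rhCerebralWhiteMatterVol: rhCerebralWhiteMatterVol
CerebralWhiteMatterVol: CerebralWhiteMatterVol
SubCortGrayVol: SubCortGrayVol
TotalGrayVol: TotalGrayVol
EstimatedTotalIntraCranialVol: eTIV
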
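# Default feature panel: the 35-region volumetric row list plus raw eTIV,
# and the six age-corrected cognitive index scores.
region_columns:
  - Left Cerebellum WM
  - Left Cerebellum Cortex
  - Left Thalamus
  - Left Caudate
  - Left Putamen
  - Left Pallidum
  - Left Hippocampus
  - Left Amygdala
  - Left Accumbens Area
  - CSF
  - Right Cerebellum WM
  - Right Cerebellum Cortex
  - Right Thalamus
  - Right Caudate
  - Right Putamen
  - Right Pallidum
  - Right Hippocampus
  - Right Amygdala
  - Right Accumbens Area
  - WM Hypointensities
  - CC Posterior
  - CC Mid Posterior
  - CC Central
  - CC Mid Anterior
  - CC Anterior
  - BrainSegVol
  - BrainSegVolNotVent
  - lhCortexVol
  - rhCortexVol
  - CortexVol
  - lhCerebralWhiteMatterVol
  - rhCerebralWhiteMatterVol
  - CerebralWhiteMatterVol
  - SubCortGrayVol
  - TotalGrayVol
cognitive_columns:
  - Full-scale RBANS
  - Memory Index
  - Visuospatial Index
  - Verbal Skills Index
  - Attention Index
  - Recall Index
include_etiv: true
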
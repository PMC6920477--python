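# Circadian panel: canonical clock genes (signal-to-noise order) followed by
# blood-rhythmicity predictor genes; duplicates collapse on load (23 unique).
PER1
NR1D2
PER3
NR1D1
PER2
ARNTL
NPAS2
CLOCK
CRY2
CRY1
DDIT4
CLEC4E
FKBP5
DAAM2
TPST1
IL13RA1
SMAP2
HNRNPDL
FOSL2
FLT3
CDC42EP2
TMEM88
RBM3
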
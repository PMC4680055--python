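method,s,r,sigma_rank
BIGR2,38,1,4
UofL BioImaging,38,2,8
CMIV,50,3,
UB VPML Med,61,4,
Bigr_neuro,64,5,
Robarts,66,6,
Narsil,71,7,
SPM_T1_F,75,8,
SPM_T1_IR,81,9,
MNAB,86,10,
SPM_T1,91,11,
FSL_Seg,99,12,
SPM_T1_IR_F,105,13,
FSL_PVSeg,107,14,
FreeSurfer,116,15,13
Jedi Mind Meld,116,16,17
S2_QM,130,17,
LNMBrains,145,18,
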
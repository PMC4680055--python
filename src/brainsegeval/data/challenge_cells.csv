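method,measure,component,rank,mean,sd
BIGR2,D,GM,1,84.7,1.3
BIGR2,H95,GM,2,1.9,0.4
BIGR2,AVD,GM,4,6.1,3.3
BIGR2,D,WM,2,88.4,1.2
BIGR2,H95,WM,2,2.4,0.5
BIGR2,AVD,WM,4,6.0,5.1
BIGR2,D,CSF,4,78.3,5.0
BIGR2,H95,CSF,5,3.2,0.8
BIGR2,AVD,CSF,14,23,17
BIGR2,D,brain,1,95.1,0.5
BIGR2,H95,brain,2,2.7,0.8
BIGR2,AVD,brain,5,3.2,1.6
BIGR2,D,ICV,8,96.0,1.3
BIGR2,H95,ICV,4,3.9,1.1
BIGR2,AVD,ICV,12,5.2,3.0
UofL BioImaging,D,GM,5,83.0,1.5
UofL BioImaging,H95,GM,1,1.7,0.3
UofL BioImaging,AVD,GM,9,8.6,5.4
UofL BioImaging,D,WM,4,87.9,2.0
UofL BioImaging,H95,WM,1,2.2,0.6
UofL BioImaging,AVD,WM,13,8.7,6.6
UofL BioImaging,D,CSF,2,78.9,4.2
UofL BioImaging,H95,CSF,2,2.7,0.5
UofL BioImaging,AVD,CSF,1,9.7,10
UofL BioImaging,D,brain,2,94.9,0.6
UofL BioImaging,H95,brain,1,2.4,0.5
UofL BioImaging,AVD,brain,12,3.9,2.0
UofL BioImaging,D,ICV,5,96.7,0.8
UofL BioImaging,H95,ICV,2,3.4,0.6
UofL BioImaging,AVD,ICV,5,1.8,2.0
CMIV,D,GM,6,82.4,1.4
CMIV,H95,GM,7,2.7,0.4
CMIV,AVD,GM,5,6.8,4.0
CMIV,D,WM,5,87.7,1.6
CMIV,H95,WM,3,2.4,0.4
CMIV,AVD,WM,10,7.3,3.8
CMIV,D,CSF,3,78.6,3.1
CMIV,H95,CSF,3,3.0,0.4
CMIV,AVD,CSF,8,14,5.9
CMIV,D,brain,5,94.5,0.5
CMIV,H95,brain,7,3.8,1.1
CMIV,AVD,brain,2,2.6,2.2
CMIV,D,ICV,4,96.8,0.8
CMIV,H95,ICV,3,3.8,1.3
CMIV,AVD,ICV,11,4.9,2.3
UB VPML Med,D,GM,4,83.3,1.3
UB VPML Med,H95,GM,4,2.1,0.3
UB VPML Med,AVD,GM,2,5.9,5.3
UB VPML Med,D,WM,1,88.6,1.7
UB VPML Med,H95,WM,5,2.7,0.4
UB VPML Med,AVD,WM,7,7.1,3.8
UB VPML Med,D,CSF,8,74.8,7.1
UB VPML Med,H95,CSF,13,4.3,1.7
UB VPML Med,AVD,CSF,17,31,19
UB VPML Med,D,brain,4,94.6,0.6
UB VPML Med,H95,brain,4,2.8,0.4
UB VPML Med,AVD,brain,1,2.4,1.8
UB VPML Med,D,ICV,10,94.8,2.0
UB VPML Med,H95,ICV,11,6.6,2.0
UB VPML Med,AVD,ICV,15,7.7,4.1
Bigr_neuro,D,GM,7,81.5,1.7
Bigr_neuro,H95,GM,13,3.7,0.9
Bigr_neuro,AVD,GM,3,5.9,4.2
Bigr_neuro,D,WM,6,87.3,1.4
Bigr_neuro,H95,WM,6,3.0,0.4
Bigr_neuro,AVD,WM,9,7.3,3.8
Bigr_neuro,D,CSF,6,78.2,4.7
Bigr_neuro,H95,CSF,4,3.2,0.6
Bigr_neuro,AVD,CSF,10,16,14
Bigr_neuro,D,brain,7,94.0,0.8
Bigr_neuro,H95,brain,10,4.6,1.4
Bigr_neuro,AVD,brain,10,3.6,2.4
Bigr_neuro,D,ICV,7,96.3,1.2
Bigr_neuro,H95,ICV,5,3.9,0.9
Bigr_neuro,AVD,ICV,8,3.5,2.7
Robarts,D,GM,11,79.7,2.4
Robarts,H95,GM,3,2.0,0.1
Robarts,AVD,GM,15,9.8,7.3
Robarts,D,WM,8,86.2,1.3
Robarts,H95,WM,8,3.1,0.4
Robarts,AVD,WM,6,7.1,6.2
Robarts,D,CSF,1,80.3,4.1
Robarts,H95,CSF,1,2.7,0.5
Robarts,AVD,CSF,13,20,13
Robarts,D,brain,16,93.1,1.6
Robarts,H95,brain,3,2.8,0.5
Robarts,AVD,brain,18,7.9,3.6
Robarts,D,ICV,1,97.9,0.3
Robarts,H95,ICV,1,2.6,0.4
Robarts,AVD,ICV,1,0.9,0.7
Narsil,D,GM,3,83.5,1.8
Narsil,H95,GM,5,2.3,0.4
Narsil,AVD,GM,1,5.5,4.4
Narsil,D,WM,7,87.1,1.3
Narsil,H95,WM,11,3.3,0.9
Narsil,AVD,WM,2,5.8,5.3
Narsil,D,CSF,17,66.6,2.4
Narsil,H95,CSF,18,13.3,5.4
Narsil,AVD,CSF,7,14,9.5
Narsil,D,brain,3,94.8,0.5
Narsil,H95,brain,5,2.9,0.5
Narsil,AVD,brain,3,2.9,2.0
Narsil,D,ICV,16,92.5,0.5
Narsil,H95,ICV,18,24,8.9
Narsil,AVD,ICV,9,3.7,1.7
SPM_T1_F,D,GM,8,81.2,2.2
SPM_T1_F,H95,GM,9,2.9,0.3
SPM_T1_F,AVD,GM,16,10,8.5
SPM_T1_F,D,WM,9,86.0,1.5
SPM_T1_F,H95,WM,7,3.0,0.1
SPM_T1_F,AVD,WM,1,5.2,3.8
SPM_T1_F,D,CSF,9,74.1,3.4
SPM_T1_F,H95,CSF,14,4.6,0.6
SPM_T1_F,AVD,CSF,2,10,4.7
SPM_T1_F,D,brain,9,93.9,1.0
SPM_T1_F,H95,brain,14,5.8,2.2
SPM_T1_F,AVD,brain,14,5.3,3.8
SPM_T1_F,D,ICV,6,96.6,0.2
SPM_T1_F,H95,ICV,14,8.2,3.0
SPM_T1_F,AVD,ICV,4,1.5,1.0
SPM_T1_IR,D,GM,12,79.4,2.1
SPM_T1_IR,H95,GM,11,3.0,0.4
SPM_T1_IR,AVD,GM,7,7.2,6.3
SPM_T1_IR,D,WM,16,83.5,2.1
SPM_T1_IR,H95,WM,12,3.6,0.3
SPM_T1_IR,AVD,WM,5,6.3,4.6
SPM_T1_IR,D,CSF,5,78.3,3.8
SPM_T1_IR,H95,CSF,10,4.0,0.6
SPM_T1_IR,AVD,CSF,3,10,5.7
SPM_T1_IR,D,brain,8,93.9,0.8
SPM_T1_IR,H95,brain,11,4.6,1.2
SPM_T1_IR,AVD,brain,7,3.4,2.8
SPM_T1_IR,D,ICV,2,97.7,0.2
SPM_T1_IR,H95,ICV,8,6.5,1.3
SPM_T1_IR,AVD,ICV,2,1.0,0.8
MNAB,D,GM,2,83.9,2.1
MNAB,H95,GM,8,2.8,0.9
MNAB,AVD,GM,12,9.1,6.5
MNAB,D,WM,3,88.0,1.2
MNAB,H95,WM,4,2.7,0.8
MNAB,AVD,WM,11,7.8,4.0
MNAB,D,CSF,15,68.1,4.0
MNAB,H95,CSF,15,4.9,2.2
MNAB,AVD,CSF,16,29,21
MNAB,D,brain,6,94.5,1.0
MNAB,H95,brain,9,4.5,2.0
MNAB,AVD,brain,11,3.8,3.2
MNAB,D,ICV,15,92.5,1.1
MNAB,H95,ICV,12,7.1,4.2
MNAB,AVD,ICV,17,9.7,4.7
SPM_T1,D,GM,9,80.3,2.4
SPM_T1,H95,GM,10,3.0,0.5
SPM_T1,AVD,GM,6,6.9,6.8
SPM_T1,D,WM,11,85.6,1.7
SPM_T1,H95,WM,10,3.1,0.1
SPM_T1,AVD,WM,3,6.0,4.1
SPM_T1,D,CSF,11,70.7,3.8
SPM_T1,H95,CSF,16,5.3,1.5
SPM_T1,AVD,CSF,15,23,15.7
SPM_T1,D,brain,10,93.9,0.9
SPM_T1,H95,brain,8,4.4,1.6
SPM_T1,AVD,brain,6,3.2,2.9
SPM_T1,D,ICV,9,95.3,0.9
SPM_T1,H95,ICV,13,8.1,3.7
SPM_T1,AVD,ICV,13,5.5,3.7
FSL_Seg,D,GM,13,78.7,2.2
FSL_Seg,H95,GM,16,4.3,1.2
FSL_Seg,AVD,GM,10,8.6,6.3
FSL_Seg,D,WM,10,86.0,2.6
FSL_Seg,H95,WM,13,3.7,0.8
FSL_Seg,AVD,WM,14,11.5,6.3
FSL_Seg,D,CSF,12,69.9,2.8
FSL_Seg,H95,CSF,6,3.4,0.2
FSL_Seg,AVD,CSF,5,12,10.3
FSL_Seg,D,brain,13,93.3,0.8
FSL_Seg,H95,brain,13,5.5,1.4
FSL_Seg,AVD,brain,4,3.0,1.5
FSL_Seg,D,ICV,12,94.2,0.8
FSL_Seg,H95,ICV,6,5.3,1.1
FSL_Seg,AVD,ICV,6,3.4,1.5
SPM_T1_IR_F,D,GM,10,80.1,2.4
SPM_T1_IR_F,H95,GM,12,3.0,0.2
SPM_T1_IR_F,AVD,GM,18,13.9,9.6
SPM_T1_IR_F,D,WM,15,83.6,2.1
SPM_T1_IR_F,H95,WM,14,3.8,0.5
SPM_T1_IR_F,AVD,WM,12,8.4,5.2
SPM_T1_IR_F,D,CSF,7,76.9,3.1
SPM_T1_IR_F,H95,CSF,11,4.1,0.5
SPM_T1_IR_F,AVD,CSF,6,12,6.0
SPM_T1_IR_F,D,brain,12,93.6,1.1
SPM_T1_IR_F,H95,brain,15,5.9,1.8
SPM_T1_IR_F,AVD,brain,13,5.1,3.6
SPM_T1_IR_F,D,ICV,3,97.7,0.2
SPM_T1_IR_F,H95,ICV,15,8.2,1.8
SPM_T1_IR_F,AVD,ICV,3,1.2,0.9
FSL_PVSeg,D,GM,15,77.7,2.6
FSL_PVSeg,H95,GM,15,4.3,1.3
FSL_PVSeg,AVD,GM,8,8.4,6.5
FSL_PVSeg,D,WM,13,84.8,3.2
FSL_PVSeg,H95,WM,15,3.8,0.9
FSL_PVSeg,AVD,WM,17,19.7,10
FSL_PVSeg,D,CSF,13,69.5,2.2
FSL_PVSeg,H95,CSF,7,3.4,0.3
FSL_PVSeg,AVD,CSF,4,11,5.8
FSL_PVSeg,D,brain,11,93.6,0.9
FSL_PVSeg,H95,brain,16,6.1,1.6
FSL_PVSeg,AVD,brain,9,3.5,3.0
FSL_PVSeg,D,ICV,13,94.2,0.8
FSL_PVSeg,H95,ICV,7,5.3,1.1
FSL_PVSeg,AVD,ICV,7,3.4,1.5
FreeSurfer,D,GM,16,77.4,2.0
FreeSurfer,H95,GM,6,2.3,0.6
FreeSurfer,AVD,GM,17,12.1,6.0
FreeSurfer,D,WM,12,85.2,2.2
FreeSurfer,H95,WM,9,3.1,0.5
FreeSurfer,AVD,WM,8,7.2,4.6
FreeSurfer,D,CSF,18,65.8,3.7
FreeSurfer,H95,CSF,12,4.3,0.6
FreeSurfer,AVD,CSF,18,50,19.6
FreeSurfer,D,brain,17,92.3,0.8
FreeSurfer,H95,brain,6,3.6,0.6
FreeSurfer,AVD,brain,16,6.3,3.4
FreeSurfer,D,ICV,17,92.4,0.9
FreeSurfer,H95,ICV,10,6.6,0.4
FreeSurfer,AVD,ICV,18,10,4.5
Jedi Mind Meld,D,GM,14,77.8,5.9
Jedi Mind Meld,H95,GM,14,3.9,2.8
Jedi Mind Meld,AVD,GM,11,8.9,7.6
Jedi Mind Meld,D,WM,17,80.6,9.6
Jedi Mind Meld,H95,WM,16,4.5,3.6
Jedi Mind Meld,AVD,WM,15,13.7,12
Jedi Mind Meld,D,CSF,10,73.3,3.5
Jedi Mind Meld,H95,CSF,8,3.7,0.8
Jedi Mind Meld,AVD,CSF,11,18,9.0
Jedi Mind Meld,D,brain,15,93.2,1.7
Jedi Mind Meld,H95,brain,12,5.4,4.8
Jedi Mind Meld,AVD,brain,8,3.5,3.0
Jedi Mind Meld,D,ICV,11,94.3,1.7
Jedi Mind Meld,H95,ICV,16,20,3.7
Jedi Mind Meld,AVD,ICV,14,6.8,3.1
S2_QM,D,GM,17,76.4,3.4
S2_QM,H95,GM,17,5.5,3.0
S2_QM,AVD,GM,13,9.3,6.4
S2_QM,D,WM,14,83.9,3.4
S2_QM,H95,WM,17,4.9,3.2
S2_QM,AVD,WM,18,24.8,10
S2_QM,D,CSF,16,67.9,2.3
S2_QM,H95,CSF,9,3.8,0.6
S2_QM,AVD,CSF,9,14,9.9
S2_QM,D,brain,14,93.3,1.4
S2_QM,H95,brain,17,7.0,3.5
S2_QM,AVD,brain,15,5.5,4.5
S2_QM,D,ICV,14,93.7,1.1
S2_QM,H95,ICV,9,6.5,1.4
S2_QM,AVD,ICV,10,4.0,2.2
LNMBrains,D,GM,18,72.8,5.3
LNMBrains,H95,GM,18,6.8,2.3
LNMBrains,AVD,GM,14,9.5,7.6
LNMBrains,D,WM,18,78.3,6.4
LNMBrains,H95,WM,18,6.8,3.5
LNMBrains,AVD,WM,16,15.3,13
LNMBrains,D,CSF,14,68.8,6.6
LNMBrains,H95,CSF,17,7.7,2.4
LNMBrains,AVD,CSF,12,20,13
LNMBrains,D,brain,18,88.5,4.5
LNMBrains,H95,brain,18,8.6,2.8
LNMBrains,AVD,brain,17,7.4,7.7
LNMBrains,D,ICV,18,89.2,4.8
LNMBrains,H95,ICV,17,20.4,3.7
LNMBrains,AVD,ICV,16,7.9,8.3
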
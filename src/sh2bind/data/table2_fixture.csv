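peptide_id,panel,sequence,position_label,kd_spr_uM,kd_spr_sem,ki_nmr_uM,ki_nmr_sem
GHR_WT,GHR,PVPDpYTSIHIV,WT,1.5,0.09,1.5,0.06
GHR_Vm3R,GHR,PRPDpYTSIHIV,V(-3)R,9.0,1.05,20.6,2.09
GHR_Vm3Y,GHR,PYPDpYTSIHIV,V(-3)Y,3.3,0.13,3.3,0.24
GHR_Am4,GHR,AVPDpYTSIHIV,pY(-4),1.7,0.14,0.9,0.17
GHR_Am3,GHR,PAPDpYTSIHIV,pY(-3),2.7,0.19,3.4,0.25
GHR_Am2,GHR,PVADpYTSIHIV,pY(-2),1.4,0.12,4.1,0.75
GHR_Am1,GHR,PVPApYTSIHIV,pY(-1),6.2,0.37,21.7,3.34
GHR_Ap1,GHR,PVPDpYASIHIV,pY(+1),1.0,0.09,0.5,0.07
GHR_Ap2,GHR,PVPDpYTAIHIV,pY(+2),1.4,0.07,1.2,0.06
GHR_Ap3,GHR,PVPDpYTSAHIV,pY(+3),3.7,0.22,3.4,0.66
GHR_Ap4,GHR,PVPDpYTSIAIV,pY(+4),6.7,0.78,18.5,2.67
GHR_Ap5,GHR,PVPDpYTSIHAV,pY(+5),2.4,0.13,1.4,0.36
GHR_Ap6,GHR,PVPDpYTSIHIA,pY(+6),1.9,0.09,1.6,0.21
EpoR_WT,EpoR,ASFEpYTILDPS,WT,13.3,0.59,7.1,1.01
EpoR_Am3,EpoR,AAFEpYTILDPS,pY(-3),14.2,0.65,7.5,1.04
EpoR_Am2,EpoR,ASAEpYTILDPS,pY(-2),16.3,1.02,7.2,0.42
EpoR_Am1,EpoR,ASFApYTILDPS,pY(-1),21.7,1.49,23.5,2.99
EpoR_Ap1,EpoR,ASFEpYAILDPS,pY(+1),17.1,0.38,10.3,1.28
EpoR_Ap2,EpoR,ASFEpYTALDPS,pY(+2),30.8,1.24,17.2,0.89
EpoR_Ap3,EpoR,ASFEpYTIADPS,pY(+3),32.3,1.42,20.4,0.88
EpoR_Ap4,EpoR,ASFEpYTILAPS,pY(+4),18.0,0.91,14.1,1.74
EpoR_Ap5,EpoR,ASFEpYTILDAS,pY(+5),8.9,1.25,6.9,1.39
EpoR_Ap6,EpoR,ASFEpYTILDPA,pY(+6),16.4,0.29,11.3,1.29
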
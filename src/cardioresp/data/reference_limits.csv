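index,contrast,q1,q3,low_tail_class,high_tail_class
HR,SR-CR6,0.2,5.9,reduced,increased
HR,SR-CR15,4.3,13.4,reduced,increased
QTc,SR-CR6,-0.002,0.010,reduced,increased
QTc,SR-CR15,0.005,0.019,reduced,increased
ST,SR-CR6,-0.014,0.030,reduced,increased
ST,SR-CR15,-0.027,0.032,reduced,increased
TP,SR-CR6,7681.4,19471.6,reduced,increased
TP,SR-CR15,-3419.4,327.4,reduced,increased
VLF,SR-CR6,-230.7,585.6,reduced,increased
VLF,SR-CR15,-330.3,456.0,reduced,increased
LF,SR-CR6,8402.0,18107.7,reduced,increased
LF,SR-CR15,-1762.6,-108.0,reduced,increased
LFn,SR-CR6,23.6,60.6,reduced,increased
LFn,SR-CR15,-26.8,1.4,reduced,increased
HF,SR-CR6,-1019.2,1437.2,reduced,increased
HF,SR-CR15,-1156.3,428.0,reduced,increased
HFn,SR-CR6,-59.5,-22.4,reduced,increased
HFn,SR-CR15,-2.6,26.0,reduced,increased
LFHF,SR-CR6,3.60,10.12,reduced,increased
LFHF,SR-CR15,-1.19,0.00,reduced,increased
TP_SBP,SR-CR6,9.0,58.6,reduced,increased
TP_SBP,SR-CR15,-6.2,31.2,reduced,increased
TP_DBP,SR-CR6,4.6,23.4,reduced,increased
TP_DBP,SR-CR15,-5.0,5.9,reduced,increased
VLF_SBP,SR-CR6,-6.5,13.4,reduced,increased
VLF_SBP,SR-CR15,-5.8,15.1,reduced,increased
VLF_DBP,SR-CR6,-1.4,3.7,reduced,increased
VLF_DBP,SR-CR15,-1.8,4.0,reduced,increased
LF_SBP,SR-CR6,13.6,49.0,reduced,increased
LF_SBP,SR-CR15,-4.4,4.0,reduced,increased
LF_DBP,SR-CR6,4.6,16.8,reduced,increased
LF_DBP,SR-CR15,-2.9,0.6,reduced,increased
LF_SBPn,SR-CR6,13.8,50.4,reduced,increased
LF_SBPn,SR-CR15,-34.1,-2.2,reduced,increased
LF_DBPn,SR-CR6,3.0,23.4,reduced,increased
LF_DBPn,SR-CR15,-28.1,-1.5,reduced,increased
HF_SBP,SR-CR6,-4.6,1.3,reduced,increased
HF_SBP,SR-CR15,1.4,16.1,reduced,increased
HF_DBP,SR-CR6,0.0,1.9,reduced,increased
HF_DBP,SR-CR15,-0.3,2.0,reduced,increased
HF_SBPn,SR-CR6,-49.0,-11.5,reduced,increased
HF_SBPn,SR-CR15,2.4,32.7,reduced,increased
HF_DBPn,SR-CR6,-20.9,-2.4,reduced,increased
HF_DBPn,SR-CR15,0.8,26.0,reduced,increased
LFHF_SBP,SR-CR6,2.77,13.65,reduced,increased
LFHF_SBP,SR-CR15,-1.50,-0.07,reduced,increased
LFHF_DBP,SR-CR6,0.86,7.07,reduced,increased
LFHF_DBP,SR-CR15,-2.82,-0.09,reduced,increased
TP_R,SR-CR6,45.3,711.5,reduced,increased
TP_R,SR-CR15,194.4,1684.6,reduced,increased
VLF_R,SR-CR6,3.2,15.4,reduced,increased
VLF_R,SR-CR15,0.0,6.6,reduced,increased
LF_R,SR-CR6,215.8,972.2,reduced,increased
LF_R,SR-CR15,-24.5,18.2,reduced,increased
LF_Rn,SR-CR6,59.1,82.9,reduced,increased
LF_Rn,SR-CR15,-14.1,-0.7,reduced,increased
HF_R,SR-CR6,-326.3,-74.9,reduced,increased
HF_R,SR-CR15,219.5,1744.9,reduced,increased
HF_Rn,SR-CR6,-79.7,-53.0,reduced,increased
HF_Rn,SR-CR15,2.1,20.0,reduced,increased
LFHF_R,SR-CR6,3.48,8.29,reduced,increased
LFHF_R,SR-CR15,-0.18,-0.01,reduced,increased
Ti,SR-CR6,1.7,2.9,reduced,increased
Ti,SR-CR15,-0.4,0.3,reduced,increased
Te,SR-CR6,2.3,3.6,reduced,increased
Te,SR-CR15,-0.9,0.1,reduced,increased
VT,SR-CR6,0.70,1.69,reduced,increased
VT,SR-CR15,0.12,0.68,reduced,increased
VT/TI,SR-CR6,0.02,0.17,reduced,increased
VT/TI,SR-CR15,0.10,0.36,reduced,increased
VT/TE,SR-CR6,-0.01,0.22,reduced,increased
VT/TE,SR-CR15,0.08,0.37,reduced,increased
Ti/Ttot,SR-CR6,-0.02,0.07,reduced,increased
Ti/Ttot,SR-CR15,-0.01,0.07,reduced,increased
RR,SR-CR6,-10.3,-5.5,reduced,increased
RR,SR-CR15,-1.5,3.4,reduced,increased
V,SR-CR6,0.9,6.2,reduced,increased
V,SR-CR15,3.0,10.4,reduced,increased
VO2,SR-CR6,0.04,0.28,reduced,increased
VO2,SR-CR15,0.14,0.48,reduced,increased
EDV,SR-CR6,-3.8,3.5,reduced,increased
EDV,SR-CR15,-6.4,1.8,reduced,increased
ESV,SR-CR6,-1.2,2.4,reduced,increased
ESV,SR-CR15,-1.7,2.3,reduced,increased
SV,SR-CR6,-2.8,1.7,reduced,increased
SV,SR-CR15,-5.3,0.1,reduced,increased
CO,SR-CR6,0.0,0.4,reduced,increased
CO,SR-CR15,0.1,0.7,reduced,increased
CI,SR-CR6,0.000,0.203,reduced,increased
CI,SR-CR15,0.059,0.353,reduced,increased
GPVR,SR-CR6,-170.4,6.5,reduced,increased
GPVR,SR-CR15,-262.3,-32.2,reduced,increased
SI_stroke,SR-CR6,-1.49,0.89,reduced,increased
SI_stroke,SR-CR15,-2.85,0.10,reduced,increased
VSI,SR-CR6,-0.255,-0.051,reduced,increased
VSI,SR-CR15,-0.358,-0.128,reduced,increased
HI,SR-CR6,4.98,7.26,reduced,increased
HI,SR-CR15,-0.82,1.08,reduced,increased
BR_LF,SR-CR6,0.57,10.15,reduced,increased
BR_LF,SR-CR15,-9.11,-1.52,reduced,increased
BR_HF,SR-CR6,-3.89,9.20,reduced,increased
BR_HF,SR-CR15,-11.86,-2.82,reduced,increased
IC_HR,SR-CR6,3.37,10.92,reduced,increased
IC_HR,SR-CR15,-1.11,0.41,reduced,increased
IC_SBP,SR-CR6,2.69,19.93,reduced,increased
IC_SBP,SR-CR15,-6.36,0.10,reduced,increased
IC_DBP,SR-CR6,-2.23,7.74,reduced,increased
IC_DBP,SR-CR15,-6.65,1.03,reduced,increased
IC_R,SR-CR6,3.58,8.46,reduced,increased
IC_R,SR-CR15,-0.22,-0.01,reduced,increased
ABI,SR-CR6,-18.16,-1.70,reduced,increased
ABI,SR-CR15,-6.85,11.94,reduced,increased
SRAI,SR-CR6,-2.08,-0.39,reduced,increased
SRAI,SR-CR15,0.03,2.11,reduced,increased
ARI,SR-CR6,-3.45,0.26,reduced,increased
ARI,SR-CR15,-1.18,2.37,reduced,increased
SI,SR-CR6,-105.23,-7.31,reduced,increased
SI,SR-CR15,-26.51,90.98,reduced,increased
SDANN,SR-CR6,41.02,79.39,reduced,increased
SDANN,SR-CR15,-24.62,2.05,reduced,increased
RMSSD,SR-CR6,0.26,35.57,reduced,increased
RMSSD,SR-CR15,-13.94,19.37,reduced,increased
pNN50,SR-CR6,-1.29,7.80,reduced,increased
pNN50,SR-CR15,-2.35,-0.13,reduced,increased
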
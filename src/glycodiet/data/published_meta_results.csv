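trait_code,period,effect,se,p_value,p_adjusted
AF,T1T2,0.34665,0.03467,1.54e-23,4.93e-22
LB,T1T2,0.33330,0.03409,1.41e-22,2.26e-21
G3,T1T2,-0.39682,0.04733,5.12e-17,4.10e-16
HB,T1T2,-0.28782,0.03800,3.63e-14,2.32e-13
S3,T1T2,-0.29167,0.03965,1.89e-13,1.01e-12
HM,T1T2,-0.20367,0.03733,4.86e-08,2.22e-07
S4,T1T2,0.21731,0.04171,1.88e-07,7.54e-07
G4,T1T2,0.20656,0.04120,5.34e-07,1.90e-06
G2,T1T2,0.18442,0.04181,1.03e-05,3.29e-05
B,T1T2,0.11955,0.03034,8.13e-05,2.36e-04
CF,T1T2,0.11460,0.04003,0.00419,0.00959
G1,T1T2,0.09387,0.04375,0.03190,0.05373
S0,T1T2,0.08067,0.04394,0.06639,0.09657
S1,T1T2,0.02901,0.03133,0.35451,0.45377
S2,T1T2,0.01949,0.04570,0.66983,0.71448
G0,T1T2,0.01454,0.03687,0.69331,0.71567
AF,T2T3,-0.45084,0.04737,1.79e-21,1.905e-20
G4,T2T3,-0.16539,0.05396,0.00218,0.00580
S4,T2T3,-0.16587,0.05526,0.00269,0.00661
G3,T2T3,0.17495,0.06677,0.00878,0.01873
G2,T2T3,-0.18253,0.07246,0.01176,0.02353
LB,T2T3,-0.11801,0.04941,0.01693,0.03186
HM,T2T3,0.23105,0.10521,0.02809,0.04994
S1,T2T3,0.07768,0.03809,0.04144,0.06630
HB,T2T3,0.09861,0.05152,0.05560,0.08472
S3,T2T3,0.08903,0.06291,0.15702,0.21847
S2,T2T3,-0.15549,0.11186,0.16449,0.21932
S0,T2T3,0.08276,0.10077,0.41152,0.50649
G1,T2T3,0.07344,0.09667,0.44741,0.51133
G0,T2T3,0.06073,0.07868,0.44021,0.51133
B,T2T3,0.05390,0.07715,0.48477,0.53492
CF,T2T3,0.01978,0.09589,0.83656,0.83656
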
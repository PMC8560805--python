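line_id,group,ciliogenesis_pct,ciliogenesis_sd,length_um,length_sd,ift_um2,ift_sd
control_1,control,88,11,3.31,0.10,0.41,0.02
control_2,control,87,11,4.11,0.12,0.45,0.01
control_3,control,93,5,3.84,0.10,0.43,0.03
control_4,control,88,10,4.15,0.14,0.36,0.03
control_5,control,94,5,3.42,0.11,0.44,0.03
control_6,control,89,8,3.54,0.14,0.45,0.02
patient_1,CED,88,8,2.60,0.08,1.10,0.06
patient_2,CED,83,17,2.48,0.11,0.67,0.03
patient_3,CED,68,17,2.18,0.09,0.74,0.07
patient_4,CEDL,90,9,2.91,0.10,1.24,0.08
patient_5,ATD,89,8,4.73,0.08,0.51,0.05
patient_6,ATD,92,7,4.94,0.13,0.79,0.04
patient_7,ATD,93,5,4.84,0.10,0.42,0.02
patient_8,ATD,94,7,5.01,0.20,0.54,0.03
patient_9,ATD,96,4,4.69,0.11,0.47,0.02
patient_10,SRPS,71,13,2.30,0.12,0.85,0.05
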
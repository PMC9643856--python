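category,label,hr_pfs,hr_pfs_lo,hr_pfs_hi,hr_os,hr_os_lo,hr_os_hi
Sex,Male,0.72,0.57,0.90,0.72,0.57,0.92
Sex,Female,0.55,0.33,0.90,0.62,0.37,1.05
Age,<65 years,0.70,0.54,0.91,0.71,0.54,0.93
Age,>=65 years,0.62,0.43,0.89,0.70,0.48,1.00
ECOG performance status,0,0.62,0.35,1.10,0.83,0.46,1.52
ECOG performance status,1,0.69,0.56,0.87,0.69,0.55,0.87
Smoking history,Current or former smoker,0.76,0.60,0.96,0.75,0.59,0.95
Smoking history,Never smoked,0.44,0.27,0.71,0.59,0.37,0.95
LDH concentration at enrolment,<=ULN,0.70,0.52,0.95,0.59,0.42,0.82
LDH concentration at enrolment,>ULN,0.64,0.48,0.85,0.83,0.62,1.11
Liver metastases,Yes,0.74,0.51,1.07,0.92,0.65,1.31
Liver metastases,No,0.64,0.50,0.83,0.61,0.46,0.81
Brain metastases,No,0.65,0.53,0.81,0.68,0.55,0.85
Disease stage,IV,0.68,0.55,0.83,0.72,0.58,0.90
PD-L1 tumour proportion score,<1%,0.68,0.54,0.85,0.66,0.52,0.83
PD-L1 tumour proportion score,>=1%,0.70,0.34,1.45,0.72,0.33,1.59
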
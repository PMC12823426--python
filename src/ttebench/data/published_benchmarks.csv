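study,endpoint,primary,hr_rwe,ci_low_rwe,ci_high_rwe,hr_trial,ci_low_trial,ci_high_trial
SUSTAIN-6,MACE,1,0.68,0.60,0.77,0.74,0.58,0.95
SUSTAIN-6,Myocardial infarction,0,0.70,0.57,0.86,0.74,0.51,1.08
SUSTAIN-6,Stroke,0,0.82,0.65,1.03,0.61,0.38,0.99
SUSTAIN-6,All-cause mortality,0,0.58,0.48,0.71,1.05,0.74,1.50
SURPASS-CVOT,MACE,1,0.83,0.69,1.01,0.92,0.83,1.01
SURPASS-CVOT,Myocardial infarction,0,0.81,0.61,1.06,0.86,0.74,1.00
SURPASS-CVOT,Stroke,0,0.92,0.65,1.29,0.91,0.76,1.09
SURPASS-CVOT,All-cause mortality,0,0.76,0.52,1.11,0.84,0.75,0.94
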
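# Published pooled cause-specific mortality ratios vs current coverage (the
# 0% reference column) at percentage-point shifts of FHS coverage. Used by
# examples to back out the pooled hazard ratio each row implies.
cause,-20%,-10%,0%,10%,20%,30%,40%
All causes,1.11,1.05,1.00,0.95,0.89,0.84,0.78
Infections (excluding HIV, TB, malaria, NTDs),1.11,1.05,1.00,0.95,0.89,0.84,0.79
HIV,1.08,1.04,1.00,0.96,0.92,0.88,0.84
"TB, malaria, NTDs",1.03,1.02,1.00,0.98,0.97,0.95,0.94
Respiratory,1.10,1.05,1.00,0.95,0.90,0.85,0.80
Nutrition,1.08,1.04,1.00,0.96,0.92,0.87,0.83
Neoplasms,1.11,1.05,1.00,0.95,0.89,0.84,0.78
Nervous system,1.06,1.03,1.00,0.97,0.94,0.92,0.89
Endocrine,1.11,1.05,1.00,0.95,0.89,0.84,0.79
Mental/substance use,1.10,1.05,1.00,0.95,0.90,0.84,0.79
Stroke,1.14,1.07,1.00,0.93,0.86,0.80,0.73
Heart disease,1.11,1.05,1.00,0.95,0.89,0.84,0.79
Other cardiovascular,1.13,1.06,1.00,0.94,0.87,0.81,0.74
Digestive,1.10,1.05,1.00,0.95,0.90,0.84,0.79
Genitourinary,1.10,1.05,1.00,0.95,0.90,0.86,0.81
Unintentional injuries,1.13,1.07,1.00,0.93,0.87,0.80,0.74
Intentional injuries,1.16,1.08,1.00,0.92,0.84,0.75,0.67
Maternal,1.01,1.00,1.00,1.00,0.99,0.99,0.99
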
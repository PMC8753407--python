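# SYNTHETIC DEFAULT adult cause-of-death mix (fractions of all-cause adult
# mortality; sum to 1). The published city table prints only all-cause
# mortality, so cause-specific baselines are generated around this plausible
# urban-Brazil mix (cardiovascular-dominant, substantial injury share).
cause,fraction
infections_other,0.045
hiv,0.01
tb_malaria_ntd,0.005
respiratory,0.10
nutrition,0.01
neoplasms,0.18
nervous_system,0.03
endocrine,0.06
mental_substance,0.01
stroke,0.10
heart_disease,0.20
other_cvd,0.08
digestive,0.05
genitourinary,0.02
unintentional_injury,0.06
intentional_injury,0.035
maternal,0.005
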
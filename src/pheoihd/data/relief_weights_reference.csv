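feature,weight
ctvalue,-2.8871
prevma,-3.3417
arrhythmia,-4.4444
age,-4.6933
bmi,-6.7295
size,-9.2895
asa,-13.3596
preblood,-19.3992
hypertension,-22.7188
dm,-23.1212
necrosis,-24.2869
surgeryapproach,-26.2391
preablock,-27.0017
chd,-27.0591
precrystal,-27.1358
precolloid,-27.1396
side,-27.5089
sex,-28.2274
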
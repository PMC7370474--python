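feature,mda,mdg,relief
bmi,19.3095,16.688,-6.7295
size,9.6143,12.2722,-9.2895
asa,5.7061,2.3838,-13.3596
hypertension,4.6416,2.9614,-22.7188
ctvalue,4.6293,9.3884,-2.8871
prevma,1.3311,9.5934,-3.3417
preblood,0.8616,1.5554,-19.3992
arrhythmia,0.2419,0.3524,-4.4444
dm,0.0276,1.2103,-23.1212
age,-0.4422,8.0945,-4.6933
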
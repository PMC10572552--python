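trait	stratum	n	mean	sd
age	low	262	45	10
age	average	233	47	11
age	high	119	47	10
bmi	low	262	24.5	3.7
bmi	average	233	24.3	3.3
bmi	high	119	24.0	3.3
cholesterol	low	262	192	36
cholesterol	average	233	199	37
cholesterol	high	119	207	37
ldl	low	262	109	30
ldl	average	233	117	33
ldl	high	119	127	35
hdl	low	262	55	15
hdl	average	233	55	15
hdl	high	119	55	13
triglyceride	low	262	153	148
triglyceride	average	233	139	91
triglyceride	high	119	124	83
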
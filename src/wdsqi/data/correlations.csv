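indicator,pH,SOM,AN,AP,AK,TP,TN,SMC,BD
pH,1,-0.386,-0.535,-0.603,-0.645,-0.735,-0.532,-0.500,-0.761
SOM,-0.386,1,0.735,0.841,0.832,0.633,0.658,0.589,0.330
AN,-0.535,0.735,1,0.542,0.566,0.497,0.628,0.652,0.518
AP,-0.603,0.841,0.542,1,0.763,0.533,0.487,0.457,0.262
AK,-0.645,0.832,0.566,0.763,1,0.574,0.487,0.472,0.299
TP,-0.735,0.633,0.497,0.533,0.574,1,0.689,0.546,0.533
TN,-0.532,0.658,0.628,0.487,0.487,0.689,1,0.658,0.679
SMC,-0.500,0.589,0.652,0.457,0.472,0.546,0.658,1,0.522
BD,-0.761,0.330,0.518,0.262,0.299,0.533,0.679,0.522,1
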
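indicator,pc1,pc2,printed_group,printed_norm
SOM,0.899,-0.325,1,4.520
AN,0.801,-0.412,1,3.691
TN,0.795,0.386,1,3.614
AP,0.780,0.098,1,3.318
AK,0.779,-0.476,1,3.571
SMC,0.719,0.284,1,2.907
TP,0.784,0.111,1,3.355
pH,-0.815,0.872,1,4.521
BD,0.585,0.665,2,2.392
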
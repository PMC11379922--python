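indicator,tds_communality,tds_weight,mds_communality,mds_weight
pH,0.672,0.101,0.702,0.339
SOM,0.914,0.138,0.826,0.399
AP,0.811,0.122,,
AN,0.618,0.093,,
AK,0.833,0.125,,
BD,0.785,0.118,0.540,0.261
SMC,0.598,0.090,,
TP,0.627,0.094,,
TN,0.780,0.118,,
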
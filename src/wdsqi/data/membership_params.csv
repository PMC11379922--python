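name,units,fn_kind,p1,p2,p3,p4
pH,pH units,parabolic,5.5,6.5,7.5,8.5
SOM,g·kg-1,s_type,4,13,,
AN,mg·kg-1,s_type,5,15,,
AP,mg·kg-1,s_type,3,10,,
AK,mg·kg-1,s_type,100,380,,
TP,g·kg-1,s_type,1,2,,
TN,g·kg-1,s_type,1,2.5,,
SMC,%,parabolic,5.25,8,10,16
BD,g·kg-1,parabolic,0.55,0.75,0.85,1.25
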
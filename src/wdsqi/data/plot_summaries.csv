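plot_id,indicator,mean,sd
No.1,pH,8.294,0.294
No.1,SOM,12.160,2.69
No.1,AN,13.69,3.317
No.1,AP,8.326,1.225
No.1,AK,399.00,35.164
No.1,TP,1.870,0.42
No.1,TN,2.455,0.346
No.1,SMC,9.868,3.021
No.1,BD,0.778,0.181
No.2,pH,8.494,0.190
No.2,SOM,11.640,1.50
No.2,AN,12.622,2.440
No.2,AP,7.778,2.168
No.2,AK,388.40,26.17
No.2,TP,1.746,0.41
No.2,TN,1.816,0.485
No.2,SMC,8.534,3.247
No.2,BD,0.548,0.285
No.3,pH,8.80,0.470
No.3,SOM,5.160,1.1415
No.3,AN,6.078,0.689
No.3,AP,5.544,1.234
No.3,AK,303.60,43.28
No.3,TP,0.954,0.44
No.3,TN,0.982,0.531
No.3,SMC,6.178,2.852
No.3,BD,0.586,0.171
No.4_upper,pH,8.89,0.153
No.4_upper,SOM,4.12,0.356
No.4_upper,AN,5.392,1.559
No.4_upper,AP,4.884,0.876
No.4_upper,AK,259.00,34.45
No.4_upper,TP,0.804,0.48
No.4_upper,TN,0.966,0.582
No.4_upper,SMC,6.356,2.704
No.4_upper,BD,0.594,0.154
No.4_lower,pH,8.267,0.117
No.4_lower,SOM,12.280,1.77
No.4_lower,AN,11.348,2.560
No.4_lower,AP,9.130,2.173
No.4_lower,AK,397.60,18.12
No.4_lower,TP,2.308,0.42
No.4_lower,TN,2.766,0.2115
No.4_lower,SMC,10.282,3.296
No.4_lower,BD,0.886,0.156
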
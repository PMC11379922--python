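plot_id,sample_id,pH,SOM,AN,AP,AK,TN,TP,SMC,BD
No.1,F-1-1,0.24,1.00,1.00,1.00,1.00,1.00,1.00,0.27,0.71
No.1,F-1-2,0.37,1.00,1.00,0.86,1.00,1.00,0.98,1.00,0.98
No.1,F-1-3,0.13,0.95,0.72,0.76,1.00,0.90,0.65,0.98,0.10
No.1,F-1-4,0.26,0.61,0.78,0.71,0.92,0.95,0.60,0.64,0.87
No.1,F-1-5,0.42,0.70,0.53,0.59,1.00,0.69,0.67,1.00,1.00
No.2,S-2-1,0.16,0.97,0.94,1.00,0.92,1.00,1.00,0.43,0.96
No.2,S-2-2,0.11,1.00,1.00,0.40,1.00,0.54,0.78,1.00,0.10
No.2,S-2-3,0.20,0.73,0.86,0.57,1.00,0.45,0.70,0.79,0.15
No.2,S-2-4,0.10,0.68,0.63,0.63,1.00,0.47,0.34,0.39,1.00
No.2,S-2-5,0.24,0.92,0.49,0.84,0.96,0.39,0.60,0.34,0.10
No.3,T-3-1,0.10,0.23,0.28,0.50,0.73,0.31,0.22,1.00,0.33
No.3,T-3-2,0.10,0.16,0.20,0.47,0.54,0.10,0.60,0.10,0.15
No.3,T-3-3,0.10,0.39,0.17,0.10,0.92,0.10,0.10,0.10,0.64
No.3,T-3-4,0.54,0.22,0.22,0.37,0.77,0.50,0.10,0.27,1.00
No.3,T-3-5,0.10,0.10,0.11,0.61,0.81,1.00,0.10,1.00,0.10
No.4_upper,F-4-1,0.10,0.15,0.10,0.40,0.76,0.52,0.10,1.00,0.15
No.4_upper,F-4-2,0.10,0.10,0.20,0.25,0.69,0.10,0.12,0.10,0.46
No.4_upper,F-4-3,0.10,0.14,0.34,0.22,0.60,0.15,0.46,0.10,0.10
No.4_upper,F-4-4,0.10,0.12,0.10,0.33,0.50,0.10,0.10,1.00,1.00
No.4_upper,F-4-5,0.10,0.10,0.10,0.50,0.53,0.10,0.10,0.10,0.28
No.4_lower,F-5-1,0.38,0.97,0.83,0.95,1.00,1.00,1.00,0.13,0.39
No.4_lower,F-5-2,0.23,0.88,0.99,0.71,1.00,1.00,0.98,0.73,0.91
No.4_lower,F-5-3,0.18,1.00,0.45,0.61,1.00,1.00,1.00,1.00,1.00
No.4_lower,F-5-4,0.32,1.00,0.47,1.00,1.00,1.00,0.84,0.93,0.75
No.4_lower,F-5-5,0.44,0.65,0.62,0.82,1.00,1.00,1.00,1.00,1.00
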
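C1,C2,X1,D11,sd11,D12,sd12,D21,sd21,D22,sd22
0.0000,0.0100,0.000,0.940,0.005,-0.039,0.035,0.099,0.020,0.436,0.010
0.0025,0.0075,0.250,0.929,0.007,-0.030,0.030,0.057,0.010,0.443,0.006
0.0050,0.0050,0.500,1.009,0.006,-0.220,0.040,0.050,0.025,0.446,0.009
0.0075,0.0025,0.750,1.042,0.003,-0.209,0.030,0.019,0.010,0.456,0.010
0.0100,0.0000,1.000,1.055,0.002,-0.232,0.020,0.034,0.010,0.467,0.009
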
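C1,C2,X1,D11,sd11,D12,sd12,D21,sd21,D22,sd22
0.0000,0.0100,0.000,0.979,0.010,0.047,0.020,0.099,0.025,0.711,0.016
0.0025,0.0075,0.250,1.001,0.015,0.060,0.020,0.070,0.015,0.700,0.005
0.0050,0.0050,0.500,1.034,0.010,0.076,0.025,0.055,0.012,0.660,0.010
0.0075,0.0025,0.750,1.067,0.011,0.410,0.020,0.044,0.009,0.599,0.008
0.0100,0.0000,1.000,1.096,0.025,1.201,0.046,0.034,0.020,0.499,0.020
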
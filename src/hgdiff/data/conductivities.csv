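ion,z,lambda0,D0_printed
Na+,1,0.00501,1.334
Sal-,-1,0.00345,0.918
EtRA4-,-4,0.02293,0.384
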
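species,D
Sal-,0.918
beta-CD,0.436
Sal-beta-CD,0.421
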
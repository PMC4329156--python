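slope_class,width_m,reduction_fraction
SL1,2,0.13
SL1,6,0.29
SL1,10,0.42
SL1,15,0.52
SL1,20,0.60
SL2,2,0.18
SL2,6,0.36
SL2,10,0.48
SL2,15,0.58
SL2,20,0.65
SL3,2,0.27
SL3,6,0.46
SL3,10,0.58
SL3,15,0.66
SL3,20,0.72
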
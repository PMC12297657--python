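measure,value
mean,375.83
sd,65.42
median,382.00
range,159
variance,4279.77
min,298
max,457
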
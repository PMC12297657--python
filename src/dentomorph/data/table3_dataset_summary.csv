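condition,count
Caries,457
Calculus,389
Gingivitis,412
Tooth Discoloration,375
Ulcers,298
Hypodontia,324
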
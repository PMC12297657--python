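metric,mean_improvement,ci_lower,ci_upper
mAP,0.0694,0.0608,0.0780
Precision,0.0606,0.0523,0.0689
Recall,0.0736,0.0651,0.0821
F1-Score,0.0678,0.0597,0.0759
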
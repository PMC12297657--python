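metric,mean_difference,t_statistic
mAP,0.0694,17.35
Precision,0.0606,15.92
Recall,0.0736,18.67
F1-Score,0.0678,17.89
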
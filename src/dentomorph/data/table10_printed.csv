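comparison,is_gap,fid_gap,ssim_gap,psnr_gap
vs_average,11.0,-34.8,3.7,8.5
vs_lowest,20.5,-48.2,7.9,15.7
top3_vs_bottom3,11.2,-42.7,5.9,10.8
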
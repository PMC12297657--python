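metric,mean,sd,min,max
is,8.89,0.53,8.19,9.87
fid,6.46,1.20,4.21,8.12
ssim,0.918,0.022,0.882,0.952
psnr,32.05,1.46,30.05,34.76
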
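model,is,fid,ssim,psnr
Our Model,9.87,4.21,0.952,34.76
DiffusionCLIP,9.41,5.34,0.938,33.45
ControlNet-Aug,9.32,5.62,0.931,33.18
StableDiff-Aug,9.18,5.89,0.927,32.94
DDPM-Augmentor,8.95,6.14,0.923,32.41
DiffAugment,8.83,6.47,0.919,31.97
Latent Diffusion Aug,8.76,6.82,0.914,31.68
Score-SDE-Aug,8.54,7.13,0.907,31.05
DDIM-Augmentor,8.42,7.51,0.893,30.72
Guided-Diff-Aug,8.31,7.86,0.889,30.38
Noise-Aware-Aug,8.19,8.12,0.882,30.05
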
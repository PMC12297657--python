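rank,model,score
1,Our Model,1.000
2,DiffusionCLIP,0.935
3,ControlNet-Aug,0.917
4,StableDiff-Aug,0.898
5,DDPM-Augmentor,0.867
6,DiffAugment,0.843
7,Latent Diffusion Aug,0.825
8,Score-SDE-Aug,0.795
9,DDIM-Augmentor,0.768
10,Guided-Diff-Aug,0.747
11,Noise-Aware-Aug,0.728
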
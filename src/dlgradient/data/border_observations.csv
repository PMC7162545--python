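gene,genotype,x_exp,sigma_exp
sna,1x,0.17,0.02
sna,2x,0.20,0.02
sna,4x,0.19,0.02
sogv,1x,0.17,0.02
sogv,2x,0.19,0.02
sogv,4x,0.21,0.02
sogd,1x,0.45,0.02
sogd,2x,0.47,0.02
sogd,4x,0.51,0.02
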
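stage,CD4_LT_200,CD4_200_349,CD4_350_499,CD4_GE_500
CD4_LT_200,0.38,0.36,0.20,0.07
CD4_200_349,0.02,0.28,0.30,0.40
CD4_350_499,0.00,0.05,0.34,0.61
CD4_GE_500,0.00,0.02,0.22,0.76
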
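stage,CD4_LT_200,CD4_200_349,CD4_350_499,CD4_GE_500
CD4_LT_200,0.36,0.61,0.04,0.00
CD4_200_349,0.03,0.58,0.28,0.11
CD4_350_499,0.00,0.18,0.49,0.33
CD4_GE_500,0.00,0.01,0.10,0.88
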
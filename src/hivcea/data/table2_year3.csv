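stage,CD4_LT_200,CD4_200_349,CD4_350_499,CD4_GE_500
CD4_LT_200,0.57,0.43,0.00,0.00
CD4_200_349,0.11,0.32,0.43,0.14
CD4_350_499,0.00,0.10,0.38,0.52
CD4_GE_500,0.00,0.02,0.10,0.88
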
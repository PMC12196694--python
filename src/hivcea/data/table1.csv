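stage,baseline_probability,utility,initial_cost,incremental_cost
CD4_LT_200,0.39,0.67,2147.37,2025.54
CD4_200_349,0.22,0.70,2118.01,1440.75
CD4_350_499,0.16,0.71,2118.01,1406.49
CD4_GE_500,0.23,0.73,2118.01,1400.78
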
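patient_id,sensitivity,specificity,ppv,npv,accuracy,f1
IO005,0.600,0.928,0.065,0.956,0.896,0.529
469,0.857,0.324,0.522,0.846,0.479,0.490
4110,0.162,0.655,0.077,0.699,0.531,0.148
462,1.000,0.681,0.273,1.000,0.746,0.615
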
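patient_id,sensitivity,specificity,ppv,npv,accuracy,f1
466,1.000,0.354,0.452,1.000,0.500,0.475
477,1.000,1.000,0.140,1.000,1.000,1.000
IO018,0.406,0.527,0.351,0.558,0.477,0.391
4145,0.900,0.624,0.237,0.967,0.673,0.493
4124,0.909,0.641,0.132,0.985,0.667,0.345
4166,1.000,0.238,0.698,1.000,0.508,0.591
IO008,0.500,0.866,0.165,0.835,0.773,0.528
IO001,0.476,0.573,0.109,0.882,0.561,0.217
453,1.000,0.354,0.500,1.000,0.523,0.523
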
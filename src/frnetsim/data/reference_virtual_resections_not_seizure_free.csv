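patient_id,virtual_radius_mm,actual_radius_mm,soz_rr,rons_rr,fr_rr,spatial_frnet,temporal_frnet_a,temporal_frnet_b,percent_r,novel_r,virtually_seizure_free
IO005,29.85,22.40,0.818,0.821,0.776,0.000,2.222,0.207,0.600,0.800,True
IO012,,18.42,1.000,0.879,0.737,3.083,4.898,0.084,0.818,0.471,False
469,53.05,33.44,1.000,0.824,0.947,0.000,1.249,0.353,0.857,0.478,True
4110,35.08,27.11,0.318,0.191,0.833,0.000,1.282,0.088,0.162,0.905,True
462,75.66,26.06,1.000,0.906,0.429,4.360,0.894,0.262,1.000,0.600,True
IO023,74.12,9.02,1.000,0.935,0.942,0.000,1.206,0.096,0.000,1.000,True
IO013,,85.60,1.000,0.769,0.814,2.517,1.076,1.000,1.000,0.832,False
IO015,,50.24,0.625,0.992,0.915,3.261,1.629,0.099,0.000,1.000,False
IO019,,64.90,1.000,0.998,0.932,2.602,1.001,1.000,1.000,0.589,False
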
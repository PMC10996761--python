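patient_id,virtual_radius_mm,actual_radius_mm,soz_rr,rons_rr,fr_rr,spatial_frnet,temporal_frnet_a,temporal_frnet_b,percent_r,novel_r
466,45.91,26.76,1.000,0.593,0.459,1.869,0.874,0.539,1.000,0.548
477,18.57,10.77,1.000,0.880,0.845,3.561,3.905,0.406,1.000,0.000
IO018,44.09,53.98,0.563,0.750,0.661,0.666,2.376,0.545,0.406,0.395
4145,29.42,22.42,0.885,0.874,0.976,0.000,2.062,0.264,0.900,0.486
4124,28.91,20.27,1.000,0.959,0.652,1.841,1.861,1.000,0.909,0.730
4166,85.00,40.07,1.000,1.000,1.000,0.000,1.000,1.000,1.000,0.639
IO008,51.89,47.51,0.538,0.623,0.627,5.312,1.946,0.121,0.679,0.367
IO001,45.38,23.59,1.000,0.882,0.800,0.978,1.622,1.000,0.909,0.836
453,72.01,27.18,1.000,0.263,0.589,0.000,1.279,1.110,1.000,0.452
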
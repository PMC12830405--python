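group,vial,activity_dc_mbq_ml,activity_pet_acq_mbq_ml,activity_pet_fill_mbq_ml,dose_dc_gy,dose_pet_fill_gy
sirt,1,0.073,0.024,0.028,1.860,0.747
sirt,2,0.146,0.067,0.079,3.720,2.047
sirt,3,0.220,0.106,0.124,5.580,3.235
sirt,4,0.440,0.247,0.291,11.160,7.542
sirt,5,0.660,0.432,0.507,16.750,13.155
sirt,6,0.880,0.630,0.741,22.330,19.200
sirt,7,1.100,0.754,0.886,27.910,22.959
sirt,8,1.320,0.899,1.056,33.500,27.376
sirt,9,1.540,1.147,1.348,39.080,34.946
sirt,10,1.760,1.264,1.485,44.660,38.498
combination,1,0.047,0.039,0.040,1.029,1.030
combination,2,0.095,0.079,0.082,2.059,2.087
combination,3,0.143,0.120,0.126,3.088,3.176
combination,4,0.190,0.159,0.167,4.118,4.211
combination,5,0.238,0.212,0.221,5.148,5.580
combination,6,0.286,0.252,0.264,6.178,6.640
combination,7,0.330,0.330,0.345,7.207,8.687
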
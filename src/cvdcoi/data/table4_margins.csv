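outcome,category,margin,se,ci_low,ci_high,pseudo_r2
severe_disability,,0.1448,0.003754,0.1375,0.1522,0.1033
in_household_help,,0.1124,0.004209,0.1041,0.1206,0.0356
out_household_help,,0.2427,0.004543,0.2338,0.2516,0.0318
carer1,daily,0.1233,0.004540,0.1144,0.1322,0.0382
carer1,weekly,0.2812,0.006164,0.2691,0.2933,0.0382
carer1,monthly,0.2081,0.004866,0.1986,0.2176,0.0382
carer1,annually,0.3874,0.008089,0.3715,0.4033,0.0382
carer2,daily,0.0892,0.005699,0.0780,0.1003,0.0282
carer2,weekly,0.3107,0.010005,0.2910,0.3303,0.0282
carer2,monthly,0.2525,0.007954,0.2369,0.2681,0.0282
carer2,annually,0.3477,0.011712,0.3248,0.3707,0.0282
carer3,daily,0.0818,0.008625,0.0649,0.0987,0.0312
carer3,weekly,0.3016,0.015777,0.2707,0.3325,0.0312
carer3,monthly,0.2808,0.013386,0.2546,0.3070,0.0312
carer3,annually,0.3358,0.018088,0.3004,0.3713,0.0312
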
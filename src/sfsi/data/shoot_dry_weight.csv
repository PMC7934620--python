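genotype,x_lf,x_hf,pr_printed,p_value_printed,sfsi_printed
R125,110.3,142.5,22.6,0.06,0.64
R101,107.4,139.0,22.7,0.16,0.66
R052,108.3,143.9,24.8,0.14,0.71
R041,127.0,172.6,26.4,0.06,0.76
R141,113.3,153.9,26.3,0.05,0.76
Local variety,104.1,150.4,30.8,0.06,0.08
R060,97.7,142.5,31.4,0.10,0.89
R120,101.9,152.2,33.1,0.03,0.95
R100,104.4,159.4,34.5,0.04,0.97
R028,113.1,171.7,34.1,0.00,0.99
R069,92.9,142.3,34.7,0.02,1.00
R025,116.4,177.9,34.6,0.05,1.00
R133,102.3,164.2,37.7,0.01,1.08
R117,100.9,162.3,37.8,0.03,1.09
R034,101.8,167.4,39.2,0.01,1.12
R050,98.6,163.6,39.7,0.02,1.14
R056,98.0,164.5,40.4,0.01,1.16
R119,99.3,170.6,41.8,0.04,1.20
R030,84.9,148.7,42.9,0.01,1.24
R109,106.3,188.1,43.5,0.00,1.25
R131,80.1,145.4,44.9,0.02,1.30
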
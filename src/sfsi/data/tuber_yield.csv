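genotype,x_lf,x_hf,pr_printed,p_value_printed,sfsi_printed
R125,908.3,1363.8,33.4,0.05,0.64
R052,1034.6,1604.2,35.5,0.10,0.68
R060,1003.3,1587.5,36.8,0.09,0.71
R041,1010.8,1652.5,38.8,0.08,0.75
R100,944.2,1639.2,42.4,0.18,0.82
R050,882.9,1545.0,42.9,0.04,0.83
R034,1124.2,2028.3,44.6,0.01,0.86
Local variety,602.9,1099.2,45.1,0.01,0.87
R133,891.7,1775.8,49.8,0.04,0.96
R069,707.5,1419.4,50.2,0.01,0.97
R120,780.0,1572.5,50.4,0.00,0.97
R101,893.3,1860.0,52.0,0.01,1.00
R141,851.7,1842.5,53.8,0.01,1.04
R117,800.0,1799.2,55.5,0.03,1.07
R028,863.8,1974.2,56.2,0.00,1.08
R025,1205.0,2756.7,56.3,0.00,1.08
R056,863.3,1992.5,56.7,0.01,1.09
R030,571.7,1461.7,60.9,0.00,1.17
R109,795.0,2506.7,68.3,0.00,1.32
R131,367.5,1160.0,68.3,0.01,1.32
R119,755.8,2500.0,69.8,0.01,1.34
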
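# Synthetic Ratnapura-like monthly climatology (wet-zone Sri Lanka).
# Bimodal monsoon regime: southwest-monsoon peak around May, second
# intermonsoon peak around October; driest months January-February.
# Columns: calendar month, mean monthly rainfall (mm), mean number of
# rainy days (>= 2.5 mm) in the month.
month,mean_rain_mm,mean_rainy_days
1,150,13
2,120,11
3,200,15
4,350,20
5,450,22
6,350,20
7,250,17
8,250,17
9,300,18
10,480,23
11,350,20
12,200,15
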
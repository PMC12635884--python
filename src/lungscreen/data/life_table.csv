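# Synthetic abridged US-style period life table (cumulative survival from
# birth l(x), by sex) with baseline lung-cancer mortality rates per
# 100,000 person-years. Constructed for this package as a desk-scale
# stand-in for a national life table; linearly interpolated between ages.
age,surv_male,surv_female,lung_mort_male,lung_mort_female
0,1.000,1.000,0.0,0.0
5,0.993,0.994,0.0,0.0
10,0.992,0.993,0.0,0.0
15,0.991,0.992,0.0,0.0
20,0.987,0.990,0.1,0.1
25,0.982,0.988,0.2,0.2
30,0.977,0.985,0.4,0.4
35,0.971,0.982,0.7,0.7
40,0.964,0.978,3.0,2.0
45,0.955,0.973,7.0,5.0
50,0.943,0.965,15.0,12.0
55,0.925,0.952,32.0,25.0
60,0.898,0.933,60.0,45.0
65,0.860,0.905,100.0,75.0
70,0.805,0.862,150.0,110.0
75,0.725,0.797,200.0,150.0
80,0.610,0.699,240.0,180.0
85,0.455,0.557,260.0,190.0
90,0.275,0.371,250.0,180.0
95,0.115,0.180,210.0,150.0
100,0.025,0.050,170.0,120.0
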
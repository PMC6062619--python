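group,sample,size,Northern Asian,West-Central African,Omotic,Northern European,Japanese,Eastern African,Kalash,Northern African,Sino-Tibetan,Circumpolar,Amerindian,Southern Asian,Western Asian,Central African,Southeastern Asian,South Indian,Southern European,Southern African,Oceanian,Western African,Arabian
European hunter-gatherers,Western,3,0,0,0,0.601,0,0,0,0,0,0,0,0,0,0,0,0,0.372,0,0.027,0,0
European hunter-gatherers,Switzerland,1,0,0,0,0.581,0,0,0,0,0,0,0,0,0,0,0,0,0.419,0,0,0,0
European hunter-gatherers,Sweden,1,0,0,0,0.519,0,0,0,0,0,0,0.037,0,0,0,0,0,0.444,0,0,0,0
European hunter-gatherers,Motala,6,0,0,0,0.673,0,0,0,0,0,0.037,0.021,0,0,0,0,0,0.244,0,0.025,0,0
European hunter-gatherers,Eastern,3,0,0,0,0.662,0,0,0.048,0,0,0.066,0.109,0.115,0,0,0,0,0,0,0,0,0
Early Neolithic,Anatolia,2,0,0,0,0,0,0,0,0.091,0,0,0,0,0.355,0,0,0,0.437,0,0,0.011,0.106
Early Neolithic,Anatolia_Neolithic,24,0,0,0,0,0,0,0,0.069,0,0,0,0,0.345,0,0,0,0.424,0,0.006,0,0.157
Early Neolithic,Macedonia_EN,1,0,0.050,0,0,0,0,0,0.077,0,0,0,0,0.360,0,0,0,0.419,0,0,0,0.093
Early Neolithic,Macedonia_LN,2,0,0,0,0,0,0,0,0.069,0,0,0,0,0.335,0,0,0,0.463,0,0,0,0.133
Early Neolithic,Hungary_EN,10,0,0,0,0,0,0,0,0.085,0,0,0,0,0.273,0,0,0,0.486,0,0,0,0.156
Early Neolithic,LBK_EN,15,0,0,0,0,0,0,0,0.055,0,0,0,0,0.319,0,0,0,0.492,0,0,0,0.134
Early Neolithic,Iberia_EN,4,0,0,0,0,0,0,0,0.049,0,0,0,0,0.194,0,0,0,0.657,0,0,0,0.100
Eneolithic to Middle Bronze Age steppe,Samara_Eneolithic,3,0,0,0,0.644,0,0,0,0,0,0.088,0.043,0.182,0,0,0,0,0.043,0,0,0,0
Eneolithic to Middle Bronze Age steppe,Yamnaya_Kalmykia,6,0,0,0,0.551,0,0,0.064,0,0,0,0.026,0.266,0.054,0,0,0,0.039,0,0,0,0
Eneolithic to Middle Bronze Age steppe,Yamnaya_Samara,9,0,0,0,0.498,0,0,0.049,0,0,0.014,0.042,0.268,0.062,0,0,0,0.066,0,0,0,0
Eneolithic to Middle Bronze Age steppe,Afanasievo,5,0,0,0,0.526,0,0,0.023,0,0,0,0.053,0.272,0,0,0,0,0.126,0,0,0,0
Eneolithic to Middle Bronze Age steppe,Poltavka,4,0,0,0,0.537,0,0,0.065,0,0,0,0.051,0.254,0,0,0,0,0.092,0,0,0,0
Eneolithic to Middle Bronze Age steppe,Potapovka,3,0,0,0,0.546,0,0,0,0,0,0,0.063,0.256,0,0,0,0,0.135,0,0,0,0
Middle Neolithic to Copper Age Europe,Iberia_MN,4,0,0,0,0.043,0,0,0,0.093,0,0,0,0,0.130,0,0,0.021,0.668,0,0,0,0.045
Middle Neolithic to Copper Age Europe,Central_MN,6,0,0,0,0.089,0,0,0,0.025,0,0,0,0,0.243,0,0,0,0.558,0,0,0,0.084
Middle Neolithic to Copper Age Europe,Sweden,1,0,0,0,0.154,0,0,0,0.078,0,0,0,0,0.109,0,0,0,0.576,0,0,0,0.083
Middle Neolithic to Copper Age Europe,Remedello,3,0,0,0,0.102,0,0,0,0.038,0,0,0,0,0.162,0,0,0,0.622,0,0,0,0.075
Middle Neolithic to Copper Age Europe,Tyrol,1,0,0,0,0,0,0,0,0,0,0,0,0,0.292,0,0,0,0.579,0,0,0.044,0.086
Middle Neolithic to Copper Age Europe,Iberia_Chalcolithic,12,0,0,0,0.075,0,0,0,0.069,0,0,0,0,0.055,0,0,0,0.801,0,0,0,0
Middle Neolithic to Copper Age Europe,Spain,3,0,0.012,0,0.076,0,0,0,0.071,0,0,0,0,0.093,0,0.022,0,0.665,0,0,0,0.062
Middle Neolithic to Copper Age Europe,Anatolia_ChL,1,0,0,0,0,0,0,0.096,0,0,0,0,0.115,0.324,0,0.047,0,0.268,0,0,0,0.150
Bronze Age Europe,Russia_EBA,1,0,0,0,0.680,0,0,0,0,0,0,0,0.320,0,0,0,0,0,0,0,0,0
Bronze Age Europe,Northern_LNBA,10,0,0,0,0.495,0,0,0,0,0,0,0,0.094,0.057,0,0,0,0.354,0,0,0,0
Bronze Age Europe,Central_LNBA,35,0,0,0,0.450,0,0,0.030,0,0,0,0,0.132,0.054,0,0,0,0.335,0,0,0,0
Bronze Age Europe,Bell_Beaker_LN,17,0,0,0,0.460,0,0,0.017,0,0,0,0,0.047,0.040,0,0,0,0.436,0,0,0,0
Bronze Age Europe,Hungary_BA,12,0,0,0,0.390,0,0,0,0,0,0,0,0,0.093,0,0,0,0.467,0,0.017,0,0.033
Late Bronze to Iron Age steppe,Sintashta,5,0,0,0,0.553,0,0,0.058,0,0,0,0.021,0.149,0,0,0,0,0.219,0,0,0,0
Late Bronze to Iron Age steppe,Andronovo,3,0,0,0,0.454,0,0,0.063,0,0,0,0.031,0.161,0,0,0,0.028,0.264,0,0,0,0
Late Bronze to Iron Age steppe,Srubnaya,12,0,0,0,0.513,0,0,0.022,0,0,0,0.012,0.176,0.052,0,0,0,0.225,0,0,0,0
Late Bronze to Iron Age steppe,Scythia,1,0.074,0,0,0.331,0,0,0.089,0,0.057,0,0,0.207,0,0,0,0,0.242,0,0,0,0
Western Asia,Georgia,2,0.027,0,0,0.049,0,0,0.090,0,0,0,0,0.377,0.458,0,0,0,0,0,0,0,0
Western Asia,Iran_HotuIIIb,1,0,0,0,0,0,0,0.257,0,0,0,0,0.539,0,0,0,0.204,0,0,0,0,0
Western Asia,Iran_N,4,0,0,0,0,0,0,0.043,0,0,0,0,0.741,0.216,0,0,0,0,0,0,0,0
Western Asia,Iran_EN,4,0,0,0,0,0,0.018,0.059,0,0,0,0,0.533,0.264,0,0,0.095,0,0,0,0,0.031
Western Asia,Iran_LN,1,0,0,0,0,0,0,0,0,0,0,0,0.539,0.308,0,0,0.153,0,0,0,0,0
Western Asia,Iran_ChL,5,0,0,0,0,0,0,0.044,0.032,0,0,0,0.302,0.424,0,0,0.062,0,0,0,0,0.136
Western Asia,Armenia_ChL,5,0,0,0,0.124,0,0,0.027,0,0,0,0,0.233,0.374,0,0,0.020,0.138,0,0,0,0.084
Western Asia,Armenia_EBA,3,0,0,0,0,0,0,0.075,0,0,0,0,0.272,0.503,0,0,0,0.058,0,0,0,0.091
Western Asia,Armenia_MLBA,1,0,0,0,0.181,0,0,0.087,0,0,0,0.042,0.300,0.391,0,0,0,0,0,0,0,0
Western Asia,Iran_IA,1,0,0,0,0.084,0,0,0,0,0,0,0,0.310,0.427,0,0,0,0,0,0,0,0.179
Western Asia,Iran_recent,1,0,0,0,0.113,0,0,0,0,0,0,0,0.285,0.392,0,0,0,0,0,0.054,0,0.155
Western Asia,Natufian,6,0,0,0.068,0,0,0,0,0.212,0,0,0,0,0.108,0,0,0,0,0,0,0,0.612
Western Asia,Levant_N,13,0,0,0,0,0,0,0,0.161,0,0,0,0,0.121,0,0,0,0,0,0,0,0.718
Western Asia,Levant_BA,3,0,0,0,0,0,0,0,0.079,0,0,0,0.075,0.323,0,0,0,0.081,0,0.018,0,0.424
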
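group,sample,size
European hunter-gatherers,Western,3
European hunter-gatherers,Switzerland,1
European hunter-gatherers,Sweden,1
European hunter-gatherers,Motala,6
European hunter-gatherers,Eastern,3
Early Neolithic,Anatolia,2
Early Neolithic,Anatolia_Neolithic,24
Early Neolithic,Macedonia_EN,1
Early Neolithic,Macedonia_LN,2
Early Neolithic,Hungary_EN,10
Early Neolithic,LBK_EN,15
Early Neolithic,Iberia_EN,4
Eneolithic to Middle Bronze Age steppe,Samara_Eneolithic,3
Eneolithic to Middle Bronze Age steppe,Yamnaya_Kalmykia,6
Eneolithic to Middle Bronze Age steppe,Yamnaya_Samara,9
Eneolithic to Middle Bronze Age steppe,Afanasievo,5
Eneolithic to Middle Bronze Age steppe,Poltavka,4
Eneolithic to Middle Bronze Age steppe,Potapovka,3
Middle Neolithic to Copper Age Europe,Iberia_MN,4
Middle Neolithic to Copper Age Europe,Central_MN,6
Middle Neolithic to Copper Age Europe,Sweden,1
Middle Neolithic to Copper Age Europe,Remedello,3
Middle Neolithic to Copper Age Europe,Tyrol,1
Middle Neolithic to Copper Age Europe,Iberia_Chalcolithic,12
Middle Neolithic to Copper Age Europe,Spain,3
Middle Neolithic to Copper Age Europe,Anatolia_ChL,1
Bronze Age Europe,Russia_EBA,1
Bronze Age Europe,Northern_LNBA,10
Bronze Age Europe,Central_LNBA,35
Bronze Age Europe,Bell_Beaker_LN,17
Bronze Age Europe,Hungary_BA,12
Late Bronze to Iron Age steppe,Sintashta,5
Late Bronze to Iron Age steppe,Andronovo,3
Late Bronze to Iron Age steppe,Srubnaya,12
Late Bronze to Iron Age steppe,Scythia,1
Western Asia,Georgia,2
Western Asia,Iran_HotuIIIb,1
Western Asia,Iran_N,4
Western Asia,Iran_EN,4
Western Asia,Iran_LN,1
Western Asia,Iran_ChL,5
Western Asia,Armenia_ChL,5
Western Asia,Armenia_EBA,3
Western Asia,Armenia_MLBA,1
Western Asia,Iran_IA,1
Western Asia,Iran_recent,1
Western Asia,Natufian,6
Western Asia,Levant_N,13
Western Asia,Levant_BA,3
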
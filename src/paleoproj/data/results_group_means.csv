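group,ancestry,percent
European hunter-gatherers,Northern European,71.6
European hunter-gatherers,Southern European,27.4
European hunter-gatherers,Oceanian,0.9
Early Neolithic farmers,Southern European,47.2
Early Neolithic farmers,Western Asian,31.9
Early Neolithic farmers,Arabian,14.2
Early Neolithic farmers,Northern African,6.8
Early to Middle Bronze Age steppe,Northern European,54.7
Early to Middle Bronze Age steppe,Southern Asian,27.8
Early to Middle Bronze Age steppe,Southern European,7.9
Early to Middle Bronze Age steppe,Kalash,4.7
Early to Middle Bronze Age steppe,Amerindian,4.2
Early to Middle Bronze Age steppe,Western Asian,0.8
Middle Neolithic Europe,Southern European,64.2
Middle Neolithic Europe,Western Asian,18.2
Middle Neolithic Europe,Northern European,6.2
Middle Neolithic Europe,Arabian,6.2
Middle Neolithic Europe,Northern African,4.3
Middle Neolithic Europe,Oceanian,0.9
Copper Age Europe,Southern European,71.8
Copper Age Europe,Western Asian,10.9
Copper Age Europe,Northern European,7.6
Copper Age Europe,Northern African,5.6
Copper Age Europe,Arabian,4.2
Bronze Age Europe,Northern European,49.0
Bronze Age Europe,Southern European,40.0
Bronze Age Europe,Western Asian,5.9
Bronze Age Europe,Southern Asian,5.1
Late Bronze to Iron Age steppe,Northern European,50.9
Late Bronze to Iron Age steppe,Southern European,23.9
Late Bronze to Iron Age steppe,Southern Asian,17.7
Late Bronze to Iron Age steppe,Kalash,3.4
Late Bronze to Iron Age steppe,Western Asian,2.5
Late Bronze to Iron Age steppe,Amerindian,1.6
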
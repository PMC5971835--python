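species,side,line_count,tally,percent
Morelia spilota,left,17,247,92
Morelia spilota,left,18,21,8
Morelia spilota,right,17,240,89
Morelia spilota,right,18,29,11
Morelia spilota,combined,17,261,97
Morelia spilota,combined,18,8,3
Candoia aspera,left,4,10,7
Candoia aspera,left,5,131,93
Candoia aspera,right,4,7,5
Candoia aspera,right,5,133,95
Candoia aspera,combined,4,4,3
Candoia aspera,combined,5,137,97
Bitis rhinoceros,left,5,18,14
Bitis rhinoceros,left,6,113,86
Bitis rhinoceros,right,5,24,18
Bitis rhinoceros,right,6,107,82
Bitis rhinoceros,combined,5,7,5
Bitis rhinoceros,combined,6,124,95
Rhabdophis tigrinus,left,3,6,4
Rhabdophis tigrinus,left,4,150,96
Rhabdophis tigrinus,right,3,11,7
Rhabdophis tigrinus,right,4,146,93
Rhabdophis tigrinus,combined,3,4,3
Rhabdophis tigrinus,combined,4,153,97
Euprepiophis mandarinus,left,5,22,10
Euprepiophis mandarinus,left,6,200,90
Euprepiophis mandarinus,right,5,20,9
Euprepiophis mandarinus,right,6,202,91
Euprepiophis mandarinus,combined,5,6,3
Euprepiophis mandarinus,combined,6,216,97
Bogertophis subocularis,left,1,22,9
Bogertophis subocularis,left,2,215,91
Bogertophis subocularis,right,1,18,8
Bogertophis subocularis,right,2,220,92
Bogertophis subocularis,combined,1,5,2
Bogertophis subocularis,combined,2,233,98
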
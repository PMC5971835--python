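species,mean_centrum_mm,sd_mm,sd_percent
Morelia spilota,9.16,1.79,19.5
Candoia aspera,3.4,0.43,12.7
Bitis rhinoceros,9.41,1.83,19.5
Rhabdophis tigrinus,5.78,0.56,9.7
Euprepiophis mandarinus,3.99,0.4,10
Bogertophis subocularis,2.52,0.26,10.1
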
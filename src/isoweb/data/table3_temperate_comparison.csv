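lake,S,L,C,D,omnivore_fraction,herbivore_fraction,basal_fraction,latitude,fish
El Sol Mexico,261,99,0.06,2.36,0.15,0.4,0.36,tropical,Oncorhynchus mykiss
La Luna Mexico,128,56,0.06,1.75,0.06,0.41,0.39,tropical,none
Caballeros Spain,64,344,0.08,5.4,0.84,0.18,0.34,temperate,none
Cimera Spain,85,645,0.09,7.6,0.91,0.06,0.16,temperate,Salvelinus fontinalis
Grande de Gredos Spain,96,534,0.06,5.6,0.93,0.05,0.52,temperate,Salmo trutta
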
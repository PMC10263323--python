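lake,group,zone,mean_d13C,sd_d13C,mean_d15N,sd_d15N
El Sol,Oncorhynchus mykiss,pelagic,-15.3,1.54,6.63,0.37
El Sol,Lumbriculus variegatus,littoral,-12.35,1.07,1.16,0.21
El Sol,Tubifex tubifex,profundal,-18.6,0.63,2.11,1
El Sol,Physa sp.,littoral,-11.94,0.14,2.8,0.57
El Sol,Daphnia ambigua,pelagic,-21.05,0.1,3.46,0.2
El Sol,Leptodiaptomus cuauhtemoci,pelagic,-24,0.035,4.7,0.45
El Sol,Bulk zooplankton,pelagic,-23.32,0.44,5.45,0.95
El Sol,Macroalgae,littoral,-10.32,0.3,-1.55,0.21
El Sol,Macrophytes C3,littoral,-25.46,1.47,-1.1,1.5
El Sol,Macrophytes C4,littoral,-11.17,0,-1.2,0
El Sol,Bulk phytoplankton,pelagic,-18.25,3.17,1.03,1
El Sol,Limnodrilus hoffmeisteri,profundal,-22.6,0.6,-0.57,0.52
El Sol,Profundal sedimentary organic matter,profundal,-21.6,2.23,-1.2,0.37
El Sol,Littoral sedimentary organic matter,littoral,-7.35,0,-0.9,0
La Luna,Daphnia ambigua,pelagic,-28.15,1.22,3.7,1.22
La Luna,Lumbriculus variegatus,profundal,-21.6,0.035,-0.25,0.21
La Luna,Limnodrilus hoffmeisteri,profundal,-22.7,0.27,0.8,0.034
La Luna,Macroalgae,littoral,-16.8,1.01,-7.5,0.64
La Luna,Profundal sedimentary organic matter,profundal,-24.7,0.2,-0.73,0.13
La Luna,Bulk phytoplankton,pelagic,-20.04,1.78,1.96,0.72
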
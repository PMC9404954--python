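category,genus,mmc_mean,mmc_n,mmc_sd,pmm_mean,pmm_n,pmm_sd,ic_mean,ic_n,ic_sd
extant,Cercocebus,1.05,15,0.05,1.42,15,0.06,1.10,15,0.10
extant,Cercopithecus,0.95,92,0.06,1.49,103,0.08,0.97,76,0.09
extant,Chlorocebus,0.96,24,0.07,1.48,26,0.10,1.02,24,0.13
extant,Colobus,1.08,118,0.06,1.47,120,0.07,1.15,93,0.10
extant,Erythrocebus,1.04,1,,1.48,1,,1.20,1,
extant,Lophocebus,0.98,5,0.05,1.49,6,0.03,1.04,5,0.11
extant,Macaca,1.12,149,0.08,1.59,174,0.09,1.26,148,0.14
extant,Mandrillus,1.16,18,0.05,1.45,18,0.08,1.38,18,0.12
extant,Nasalis,1.09,30,0.05,1.57,29,0.08,1.12,30,0.10
extant,Papio,1.22,86,0.07,1.65,99,0.09,1.46,71,0.13
extant,Piliocolobus,1.08,15,0.05,1.47,15,0.04,1.15,15,0.09
extant,Presbytis,0.97,151,0.05,1.41,160,0.07,0.96,138,0.08
extant,Theropithecus,1.25,8,0.05,1.88,10,0.06,1.53,8,0.06
fossil,Cercopithecoides,1.18,13,0.15,1.64,18,0.15,1.27,7,0.25
fossil,Cercopithecus,0.92,2,0.03,1.51,4,0.15,0.85,2,0.04
fossil,cf. Chlorocebus,0.98,26,0.07,1.55,40,0.11,1.01,22,0.09
fossil,Colobus,1.07,55,0.09,1.44,66,0.08,1.12,46,0.10
fossil,Kuseracolobus,1.17,1,,1.65,2,0.14,,,
fossil,Libypithecus,1.14,2,0.06,1.41,2,0.10,1.35,2,0.09
fossil,Papio,1.20,32,0.10,1.72,36,0.14,1.42,21,0.24
fossil,Paracolobus,1.16,3,0.20,1.54,4,0.10,1.26,3,0.23
fossil,Parapapio,1.18,23,0.13,1.74,22,0.11,1.34,19,0.21
fossil,Pliopapio,1.20,1,,1.72,1,,1.24,1,
fossil,Procercocebus,1.13,4,0.03,1.61,5,0.03,1.42,2,0.19
fossil,Rhinocolobus,1.19,3,0.07,1.43,3,0.07,1.26,2,0.16
fossil,Soromandrillus,1.28,6,0.05,1.78,6,0.13,1.55,4,0.10
fossil,Theropithecus,1.34,6,0.03,1.34,6,0.03,1.62,5,0.06
fossil,Victoriapithecus,1.01,4,0.05,1.59,2,0.08,1.05,3,0.12
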
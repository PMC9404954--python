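pairing_id,node_label,node_type,asr_mmc,asr_pmm,divergence_ma,divergence_qualifier,fossil_genus,fossil_mmc,fossil_pmm,fossil_age_min_ma,fossil_age_max_ma,include_in_mean,include_in_direction_count
n20_victoriapithecus,20,internal,1.07,1.52,16.0,,Victoriapithecus,1.03,1.59,12.5,19.0,True,False
n28_procercocebus,28,internal,1.14,1.45,5.0,,Procercocebus,1.13,1.62,2.5,2.5,True,True
n28_soromandrillus,28,internal,1.14,1.45,5.0,,Soromandrillus,1.28,1.78,2.0,3.0,True,True
n29_procercocebus,29,internal,1.10,1.43,2.0,,Procercocebus,1.13,1.62,2.5,2.5,True,True
n30_soromandrillus,30,internal,1.18,1.45,2.5,,Soromandrillus,1.28,1.78,2.0,3.0,True,True
n31_parapapio,31,internal,1.17,1.66,2.0,,Parapapio,1.18,1.76,2.0,5.0,True,True
n31_pliopapio,31,internal,1.17,1.66,2.0,,Pliopapio,1.20,1.72,4.4,4.4,True,True
n35_paracolobus,35,internal,1.07,1.49,7.5,<,Paracolobus,1.16,1.50,2.0,6.0,True,True
n35_cercopithecoides,35,internal,1.07,1.49,7.5,<,Cercopithecoides,1.18,1.67,2.0,5.0,True,True
n35_kuseracolobus,35,internal,1.07,1.49,7.5,<,Kuseracolobus,1.17,1.75,4.0,4.4,True,True
n35_libypithecus,35,internal,1.07,1.49,7.5,<,Libypithecus,1.14,1.41,5.0,5.0,True,True
tip_chlorocebus,Chlorocebus aethiops,tip,0.96,1.48,1.0,,cf. Chlorocebus,0.98,1.56,0.1,0.6,False,True
tip_colobus,Colobus guereza,tip,1.08,1.47,1.6,<,Colobus,1.06,1.44,0.1,0.6,False,True
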
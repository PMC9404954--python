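subfamily,tribe,genus,species,n_individuals
Cercopithecinae,Cercopithecini,Cercopithecus,sp. (Andalee),30
Cercopithecinae,Cercopithecini,Cercopithecus,sp. (Upper Andalee),5
Cercopithecinae,Cercopithecini,cf. Chlorocebus,Asbole,13
Cercopithecinae,Cercopithecini,cf. Chlorocebus,sp. (Chai Baro),105
Cercopithecinae,Cercopithecini,cf. Chlorocebus,sp. (Faro Daba),223
Cercopithecinae,Papionini,Papio,hamadryas angusticeps,12
Cercopithecinae,Papionini,Papio,hamadryas robinsoni,29
Cercopithecinae,Papionini,Papio,hamadryas ssp. (Asbole),10
Cercopithecinae,Papionini,Papio,hamadryas ssp. (Chai Baro),143
Cercopithecinae,Papionini,Papio,hamadryas ursinus,1
Cercopithecinae,Papionini,Papio,izodi,7
Cercopithecinae,Papionini,Parapapio,broomi,34
Cercopithecinae,Papionini,Parapapio,jonesi,12
Cercopithecinae,Papionini,Parapapio,whitei,16
Cercopithecinae,Papionini,Pliopapio,alemui,5
Cercopithecinae,Papionini,Procercocebus,antiquus,8
Cercopithecinae,Papionini,Soromandrillus,quadratirostris,11
Cercopithecinae,Papionini,Theropithecus,oswaldi cf. darti,124
Cercopithecinae,Papionini,Theropithecus,oswaldi darti,4
Cercopithecinae,Papionini,Theropithecus,oswaldi leakeyi,12
Cercopithecinae,Papionini,Theropithecus,oswaldi oswaldi,8
Colobinae,Colobini,Cercopithecoides,kimeui,12
Colobinae,Colobini,Cercopithecoides,meaveae,2
Colobinae,Colobini,Cercopithecoides,williamsi,91
Colobinae,Colobini,Colobus,cf. guereza (Faro Daba),360
Colobinae,Colobini,Colobus,sp. (Andalee),31
Colobinae,Colobini,Colobus,sp. (Asbole),47
Colobinae,Colobini,Colobus,sp. (Upper Andalee),4
Colobinae,Colobini,Kuseracolobus,aramisi,5
Colobinae,Colobini,Kuseracolobus,hafu,14
Colobinae,Colobini,Libypithecus,markgrafi,3
Colobinae,Colobini,Microcolobus,tugenensis,1
Colobinae,Colobini,Paracolobus,chemeroni,1
Colobinae,Colobini,Paracolobus,enkorikae,8
Colobinae,Colobini,Paracolobus,mutiwa,22
Colobinae,Colobini,Rhinocolobus,turkanaensis,23
Victoriapithecinae,,Victoriapithecus,macinnesi,40
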
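subfamily,tribe,genus,species,n_individuals
Cercopithecinae,Cercopithecini,Cercopithecus,albogularis,1
Cercopithecinae,Cercopithecini,Cercopithecus,campbelli,9
Cercopithecinae,Cercopithecini,Cercopithecus,mitis,95
Cercopithecinae,Cercopithecini,Chlorocebus,aethiops,28
Cercopithecinae,Cercopithecini,Erythrocebus,patas,2
Cercopithecinae,Papionini,Cercocebus,atys,4
Cercopithecinae,Papionini,Cercocebus,galeritus,1
Cercopithecinae,Papionini,Cercocebus,torquatus,20
Cercopithecinae,Papionini,Lophocebus,albigena,3
Cercopithecinae,Papionini,Macaca,fascicularis,98
Cercopithecinae,Papionini,Macaca,mulatta,76
Cercopithecinae,Papionini,Mandrillus,leucophaeus,1
Cercopithecinae,Papionini,Mandrillus,sphinx,17
Cercopithecinae,Papionini,Papio,hamadryas,127
Cercopithecinae,Papionini,Theropithecus,gelada,10
Colobinae,Colobini,Colobus,guereza,125
Colobinae,Colobini,Nasalis,larvatus,30
Colobinae,Colobini,Piliocolobus,badius,15
Colobinae,Presbytini,Presbytis,melalophos,83
Colobinae,Presbytini,Presbytis,rubicunda,80
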
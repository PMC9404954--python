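trait,side,h2,h2_se,p_printed,n_individuals,covariate_prop,significant_covariates,h2_significant
M1 2D area,L,0.611,0.110,<0.001,461,0.353,"sex,age",True
M2 2D area,L,0.728,0.091,<0.001,537,0.413,"sex,age",True
M3 2D area,L,0.261,0.190,0.260,221,0.490,sex,False
M1 2D area,R,0.703,0.132,<0.001,440,0.281,sex,True
M2 2D area,R,0.681,0.103,<0.001,531,0.366,sex,True
M3 2D area,R,0.726,0.275,0.004,171,0.508,sex,True
IC,L,0.181,0.156,0.100,170,0.103,sex,False
IC,R,0.604,0.333,0.006,127,0.094,sex,True
MMC,L,0.001,0.141,0.496,191,0.082,"sex,age",False
PMM,L,0.491,0.093,<0.001,402,0.022,sex,True
MMC,R,0.238,0.228,0.096,140,0.044,sex,False
PMM,R,0.527,0.114,<0.001,380,0.030,sex,True
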
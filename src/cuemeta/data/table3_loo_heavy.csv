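medication,k,d_observed,d_predicted,se_predicted
Acamprosate,112,-0.007,-0.080,0.009
Baclofen,28,0.109,-0.085,0.031
Memantine,4,0.188,0.733,-0.419
Nalmefene,28,-0.135,-0.089,0.038
Naltrexone,176,-0.095,-0.100,0.020
Olanzapine,8,0.050,-0.138,0.049
Ondansetron,12,-0.144,-0.042,0.069
Quetiapine,20,-0.029,0.012,0.142
Varenicline,16,-0.146,-0.789,-0.328
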
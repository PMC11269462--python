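medication,k,d_observed,d_predicted,se_predicted
Acamprosate,56,-0.275,-0.012,0.076
Baclofen,14,-0.156,-0.185,0.111
Memantine,2,0.382,0.040,-0.099
Nalmefene,14,-0.001,-0.129,-0.063
Naltrexone,88,-0.196,0.012,-0.059
Olanzapine,4,-0.066,-0.103,0.097
Ondansetron,6,-0.094,-0.061,0.246
Quetiapine,10,-0.143,0.112,0.459
Varenicline,8,-0.096,-0.544,-0.178
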
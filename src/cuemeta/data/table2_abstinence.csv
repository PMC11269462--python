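medication,k,d,se
Acamprosate,56,-0.275,0.053
Aripiprazole,2,0.261,0.155
Baclofen,14,-0.156,0.147
Carbamazepine,2,-0.211,0.289
Gabapentin,12,-0.180,0.090
Levetiracetam,6,0.016,0.080
Memantine,2,0.382,0.388
Nalmefene,14,-0.001,0.036
Naltrexone,88,-0.196,0.049
Olanzapine,4,-0.066,0.189
Ondansetron,6,-0.094,0.093
Quetiapine,10,-0.143,0.104
Rimonabant,2,-0.114,0.095
Ritanserin,6,-0.009,0.134
Sertraline,2,-0.049,0.175
Topiramate,20,-0.183,0.065
Valproate,6,-0.004,0.139
Varenicline,8,-0.096,0.079
Zonisamide,4,-0.220,0.214
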
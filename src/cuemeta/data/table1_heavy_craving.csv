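medication,k_heavy,d_heavy,se_heavy,k_craving,d_craving,se_craving
Acamprosate,112,-0.007,0.020,4,0.048,0.140
Aripiprazole,4,-0.099,0.098,,,
Baclofen,28,0.109,0.100,10,-0.167,0.134
Carbamazepine,4,0.105,0.235,,,
Gabapentin,24,-0.495,0.113,,,
Levetiracetam,12,0.021,0.059,,,
Memantine,4,0.188,0.193,2,-0.454,0.164
Nalmefene,28,-0.135,0.030,3,-0.246,0.193
Naltrexone,176,-0.095,0.020,12,-0.238,0.077
Olanzapine,8,0.050,0.082,3,-0.363,0.187
Ondansetron,12,-0.144,0.066,1,-0.025,0.292
Quetiapine,20,-0.029,0.045,1,0.176,0.541
Rimonabant,4,-0.066,0.065,,,
Ritanserin,12,-0.088,0.089,,,
Sertraline,4,0.000,0.111,,,
Topiramate,40,-0.263,0.056,,,
Valproate,12,-0.334,0.114,,,
Varenicline,16,-0.146,0.052,4,0.141,0.148
Zonisamide,8,-0.221,0.147,,,
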
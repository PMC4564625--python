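time_point,random_forests,dlda,svm_lin,logitboost,robustboost,svm_mlp
L+5,0,0,0,0,0,0
L+4,0,0,0,0,0,0
L+3,0,0,0,0,0,0
L+2,0.125,0.25,0.125,0.125,0.125,0
L+1,0.171,0.071,0.071,0.171,0.171,0.071
L,0.105,0.022,0.149,0.188,0.105,0.359
L-1,0.214,0.065,0.130,0.3,0.192,0.192
L-2,0.444,0.417,0.194,0.444,0.472,0.5
L-3,0.418,0.382,0.282,0.418,0.418,0.482
L-4,0.475,0.413,0.388,0.475,0.413,0.475
L-5,0.688,0.438,0.563,0.688,0.688,0.688
L-6,0.368,0.467,0.3,0.567,0.567,0.567
L-7,0.375,0.375,0.75,0.5,0.75,0.625
L-8,0.5,0.333,0.583,0.5,0.75,0.333
L-9,0.333,0.333,0.833,0.333,0.833,0.5
L-10,0.5,0.75,0.75,0.5,1,0.75
L-11,0.5,0.5,1,0.5,0.5,0.5
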
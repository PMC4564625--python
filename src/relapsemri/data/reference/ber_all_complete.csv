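time_point,random_forests,dlda,svm_lin,logitboost,robustboost,svm_mlp
L+5,,,,,,
L+4,,,,,,
L+3,0,0,0,0,0,0
L+2,0,0,0,0,0,0
L+1,0,0,0,0,0,0
L,0,0.1,0.217,0,0,0.1
L-1,0,0.125,0,0,0,0.125
L-2,0.25,0.25,0.5,0.25,0.25,0.25
L-3,0.5,0.5,1,0.5,0.5,0.25
L-4,1,1,1,1,1,0.5
L-5,0.25,0.25,0.25,0.25,0.25,0.25
L-6,0.5,0,0,0.5,0.5,0
L-7,1,0,1,1,1,0
L-8,,,,,,
L-9,0,0,0,0,0,0
L-10,,,,,,
L-11,0,0,1,0,0,0
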
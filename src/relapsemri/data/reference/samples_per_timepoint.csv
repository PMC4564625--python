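time_point,complete,imputed
L+5,0,2
L+4,0,2
L+3,1,3
L+2,3,8
L+1,1,12
L,13,29
L-1,9,29
L-2,6,24
L-3,3,16
L-4,2,13
L-5,2,12
L-6,2,8
L-7,1,6
L-8,0,5
L-9,1,4
L-10,0,3
L-11,1,2
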
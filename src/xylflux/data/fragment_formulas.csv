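fragment_id,C,H,N,O,Si,S,backbone_carbons
Ala_M57,11,26,1,2,2,0,3
Ala_M159,8,20,1,0,1,0,2
Gly_M57,10,24,1,2,2,0,2
Ser_M57,17,40,1,3,3,0,3
Val_M57,13,30,1,2,2,0,5
Thr_M57,18,42,1,3,3,0,4
Asp_M57,18,40,1,4,3,0,4
Asp_M159,15,34,1,2,2,0,3
Glu_M57,19,42,1,4,3,0,5
Glu_M159,16,36,1,2,2,0,4
X5P,5,10,0,8,0,0,5
R5P,5,10,0,8,0,0,5
S7P,7,14,0,10,0,0,7
F6P,6,12,0,9,0,0,6
G6P,6,12,0,9,0,0,6
6PG,6,12,0,10,0,0,6
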
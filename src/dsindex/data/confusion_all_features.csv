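,CN,AD,FTLD,DLB,VaD
CN,105,1,4,7,1
AD,1,179,21,18,4
FTLD,5,6,70,8,3
DLB,1,7,2,35,2
VaD,0,1,0,1,22
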
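,CN,AD,FTLD,DLB,VaD
CN,79,0,0,0,0
AD,0,98,7,0,0
FTLD,0,2,40,0,1
DLB,0,1,0,9,1
VaD,0,0,0,0,13
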
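label,denominator,rank
20/10,10,1
20/20,20,2
20/25,25,3
20/30,30,4
20/40,40,5
20/50,50,6
20/60,60,7
20/70,70,8
20/80,80,9
20/100,100,10
20/125,125,11
20/200,200,12
20/400,400,13
CF,,14
HM,,15
LP,,16
NLP,,17
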
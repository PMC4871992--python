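raw_text,target
20/10,20/10
20/20,20/20
20/25,20/25
20/30,20/30
20/40,20/40
20/50,20/50
20/60,20/60
20/70,20/70
20/80,20/80
20/100,20/100
20/125,20/125
20/200,20/200
20/400,20/400
cf,CF
counting fingers,CF
count fingers,CF
cf @ 1ft,CF
cf @ 2ft,CF
cf @ 3ft,CF
cf @ 4ft,CF
cf @ 5ft,CF
cf @ 6ft,CF
cf at face,CF
hm,HM
hand motion,HM
hand motions,HM
hm @ face,HM
lp,LP
light perception,LP
lp with projection,LP
lp w/projection,LP
nlp,NLP
no light perception,NLP
j1,NEAR
j1+,NEAR
j2,NEAR
j3,NEAR
j4,NEAR
j5,NEAR
j6,NEAR
j7,NEAR
j8,NEAR
j9,NEAR
j10,NEAR
j11,NEAR
j12,NEAR
j13,NEAR
j14,NEAR
j15,NEAR
j16,NEAR
6pt print,NEAR
8pt print,NEAR
10pt print,NEAR
12pt print,NEAR
14pt print,NEAR
6 point print,NEAR
8 point print,NEAR
10 point print,NEAR
12 point print,NEAR
not tested,UNMAPPED
nt,UNMAPPED
ni,UNMAPPED
no improvement,UNMAPPED
unable,UNMAPPED
unable to test,UNMAPPED
refused,UNMAPPED
deferred,UNMAPPED
see note,UNMAPPED
prosthesis,UNMAPPED
enucleated,UNMAPPED
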
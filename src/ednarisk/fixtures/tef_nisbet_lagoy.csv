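congener,tef
naphthalene,0.001
acenaphthylene,0.001
acenaphthene,0.001
fluorene,0.001
phenanthrene,0.001
anthracene,0.01
fluoranthene,0.001
pyrene,0.001
benz[a]anthracene,0.1
chrysene,0.01
benzo[b]fluoranthene,0.1
benzo[k]fluoranthene,0.1
benzo[a]pyrene,1
"indeno[1,2,3-cd]pyrene",0.1
"dibenz[a,h]anthracene",1
benzo[ghi]perylene,0.01
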
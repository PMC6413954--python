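option,state,condition,amount
pellet,control,free,15.5
pellet,blocked,free,15.7
chow,control,free,0.2
chow,blocked,free,0.8
pellet,control,lever,7.2
pellet,blocked,lever,2.1
chow,control,lever,3.9
chow,blocked,lever,7.0
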
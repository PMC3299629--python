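ctoa,observed_inhibition
0,-21
50,-26
100,-28
200,-5
300,8
500,15
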
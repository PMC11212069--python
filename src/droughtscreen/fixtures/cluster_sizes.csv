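cluster,size
I,3
IIa,10
IIb,9
III,8
IV,5
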
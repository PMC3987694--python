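9
a00 2
a01 a03
a01 3
a00 a02 a04
a02 2
a01 a05
a03 3
a00 a04 a06
a04 4
a01 a03 a05 a07
a05 3
a02 a04 a08
a06 2
a03 a07
a07 3
a04 a06 a08
a08 2
a05 a07
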
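id,lon,lat
a00,36.0,-1.0
a01,36.5,-1.0
a02,37.0,-1.0
a03,36.0,-0.5
a04,36.5,-0.5
a05,37.0,-0.5
a06,36.0,0.0
a07,36.5,0.0
a08,37.0,0.0
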
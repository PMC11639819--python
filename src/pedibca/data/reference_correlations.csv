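parameter,weight,bmi,tbw,ffm,bf,mm,bm
weight,1.000,,,,,,
bmi,0.241,1.000,,,,,
tbw,0.161,0.296,1.000,,,,
ffm,0.277,-0.047,0.132,1.000,,,
bf,0.437,0.827,0.319,0.438,1.000,,
mm,0.160,0.175,-0.002,0.527,0.444,1.000,
bm,-0.007,0.201,-0.011,0.166,0.382,0.030,1.000
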
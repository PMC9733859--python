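CORD	I1	0	0	1	1
CORD	I2	0	0	2	2
CORD	II1	I1	I2	1	2
CORD	II2	I1	I2	1	2
CORD	II3	0	0	0	1
CORD	II4	I1	I2	2	2
CORD	II5	0	0	0	1
CORD	III1	II2	II3	0	0
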
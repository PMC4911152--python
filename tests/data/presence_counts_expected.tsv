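taxon	S1	S2	S3
t01	0	120	0
t02	40	35	30
t05	10	45	45
t06	200	0	0
t10	12	88	11
t11	0	0	250
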
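taxon	S1	S2	S3
t01	9	120	5
t02	40	35	30
t03	60	25	14
t04	3	2	1
t05	10	45	45
t06	200	0	0
t07	15	15	15
t08	99	0	0
t09	50	49	0
t10	12	88	11
t11	0	0	250
t12	33	33	33
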
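sample_id	taxon	condition	replicate
F1_30C_r1	F1	30C	1
F1_30C_r2	F1	30C	2
F1_30C_r3	F1	30C	3
F1_16C_r1	F1	16C	1
F1_16C_r2	F1	16C	2
F1_16C_r3	F1	16C	3
F1_4C_r1	F1	4C	1
F1_4C_r2	F1	4C	2
F1_4C_r3	F1	4C	3
P1_30C_r1	P1	30C	1
P1_30C_r2	P1	30C	2
P1_30C_r3	P1	30C	3
P1_16C_r1	P1	16C	1
P1_16C_r2	P1	16C	2
P1_16C_r3	P1	16C	3
P1_4C_r1	P1	4C	1
P1_4C_r2	P1	4C	2
P1_4C_r3	P1	4C	3
P2_30C_r1	P2	30C	1
P2_30C_r2	P2	30C	2
P2_30C_r3	P2	30C	3
P2_16C_r1	P2	16C	1
P2_16C_r2	P2	16C	2
P2_16C_r3	P2	16C	3
P2_4C_r1	P2	4C	1
P2_4C_r2	P2	4C	2
P2_4C_r3	P2	4C	3
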
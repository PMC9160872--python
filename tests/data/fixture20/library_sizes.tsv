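sample_id	mapped_reads
F1_30C_r1	1000000.0
F1_30C_r2	1000000.0
F1_30C_r3	1000000.0
F1_16C_r1	1000000.0
F1_16C_r2	1000000.0
F1_16C_r3	1000000.0
F1_4C_r1	1000000.0
F1_4C_r2	1000000.0
F1_4C_r3	1000000.0
P1_30C_r1	1000000.0
P1_30C_r2	1000000.0
P1_30C_r3	1000000.0
P1_16C_r1	1000000.0
P1_16C_r2	1000000.0
P1_16C_r3	1000000.0
P1_4C_r1	1000000.0
P1_4C_r2	1000000.0
P1_4C_r3	1000000.0
P2_30C_r1	1000000.0
P2_30C_r2	1000000.0
P2_30C_r3	1000000.0
P2_16C_r1	1000000.0
P2_16C_r2	1000000.0
P2_16C_r3	1000000.0
P2_4C_r1	1000000.0
P2_4C_r2	1000000.0
P2_4C_r3	1000000.0
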
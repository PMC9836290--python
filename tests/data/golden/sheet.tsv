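sample_id	condition	time_h	replicate
C1	control	1	1
C2	control	2	1
C3	control	3	1
T2	treated	2	1
T3	treated	3	1
T4	treated	4	1
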
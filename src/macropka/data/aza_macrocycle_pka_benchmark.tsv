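# Experimental vs computed stepwise macroscopic pKa for tetra-aza macrocycles 1-10.
# computed: M06-2X/def2-TZVP/SMD, proton-based thermodynamic cycle, lowest-energy
# conformer per protonation state, before any empirical correction.
# source: literature citation tag for the experimental value.
molecule	step	experimental	computed	source
1	1	11.37	10.73	ref31,ref32
1	2	8.22	3.83	ref31,ref32
1	3	1.61	-1.22	ref31,ref32
2	1	11.56	14.10	ref27
2	2	9.05	9.90	ref27
2	3	5.45	3.41	ref27
2	4	1.68	-1.90	ref27
3	1	10.50	12.25	ref31,ref32
3	2	7.27	1.73	ref31,ref32
3	3	1.37	-6.88	ref31,ref32
4	1	10.54	13.35	ref31,ref32
4	2	8.27	8.04	ref31,ref32
4	3	1.73	-4.04	ref31,ref32
5	1	11.14	10.06	ref31,ref32
5	2	7.47	3.02	ref31,ref32
6	1	10.6	12.28	ref31,ref32
6	2	7.00	3.90	ref31,ref32
6	3	0.85	-3.71	ref31,ref32
7	1	10.32	10.52	ref32
7	2	8.00	5.87	ref32
7	3	1.75	-2.15	ref32
8	1	11.16	13.92	ref27
8	2	9.46	11.13	ref27
8	3	6.91	3.61	ref27
8	4	2.17	-6.47	ref27
9	1	8.27	8.50	ref23
9	2	7.36	5.62	ref23
10	1	11.31	16.82	ref23
10	2	9.35	15.58	ref23
10	3	5.25	3.75	ref23
10	4	4.21	2.40	ref23
10	5	0.98	-5.16	ref23
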
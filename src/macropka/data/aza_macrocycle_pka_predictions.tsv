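# Predicted stepwise macroscopic pKa for previously un-synthesized tetra-aza
# macrocycles 11-14 (QM + linear empirical correction, a=0.5 b=4.22).
# Reference data only: recomputation requires external CREST/DFT runs.
molecule	step	predicted
11	1	7.73
11	2	5.83
12	1	10.06
12	2	9.11
13	1	8.52
13	2	7.14
14	1	6.67
14	2	6.39
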
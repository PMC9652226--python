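aa	pI	bulkiness	cf_helix	cf_strand
A	6.00	11.50	1.42	0.83
C	5.05	13.46	0.70	1.19
D	2.77	11.68	1.01	0.54
E	3.22	13.57	1.51	0.37
F	5.48	19.80	1.13	1.38
G	5.97	3.40	0.57	0.75
H	7.59	13.69	1.00	0.87
I	6.02	21.40	1.08	1.60
K	9.74	15.71	1.16	0.74
L	5.98	21.40	1.21	1.30
M	5.74	16.25	1.45	1.05
N	5.41	12.82	0.67	0.89
P	6.30	17.43	0.57	0.55
Q	5.65	14.45	1.11	1.10
R	10.76	14.28	0.98	0.93
S	5.68	9.47	0.77	0.75
T	5.66	15.77	0.83	1.19
V	5.96	21.57	1.06	1.70
W	5.89	21.67	1.08	1.37
Y	5.66	18.03	0.69	1.47
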
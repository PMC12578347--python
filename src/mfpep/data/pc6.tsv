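residue	hydrophobicity_kd	hydrophilicity_hw	sidechain_mass	pK1_cooh	pK2_nh3	pI
A	1.8	-0.5	15.0	2.34	9.69	6.00
C	2.5	-1.0	47.0	1.96	10.28	5.07
D	-3.5	3.0	59.0	1.88	9.60	2.77
E	-3.5	3.0	73.0	2.19	9.67	3.22
F	2.8	-2.5	91.0	1.83	9.13	5.48
G	-0.4	0.0	1.0	2.34	9.60	5.97
H	-3.2	-0.5	82.0	1.82	9.17	7.59
I	4.5	-1.8	57.0	2.36	9.60	6.02
K	-3.9	3.0	73.0	2.18	8.95	9.74
L	3.8	-1.8	57.0	2.36	9.60	5.98
M	1.9	-1.3	75.0	2.28	9.21	5.74
N	-3.5	0.2	58.0	2.02	8.80	5.41
P	-1.6	0.0	42.0	1.99	10.60	6.30
Q	-3.5	0.2	72.0	2.17	9.13	5.65
R	-4.5	3.0	101.0	2.17	9.04	10.76
S	-0.8	0.3	31.0	2.21	9.15	5.68
T	-0.7	-0.4	45.0	2.09	9.10	5.60
V	4.2	-1.5	43.0	2.32	9.62	5.96
W	-0.9	-3.4	130.0	2.83	9.39	5.89
Y	-1.3	-2.3	107.0	2.20	9.11	5.66
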
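residue	hydrophobicity_kd	hydrophilicity_hw	sidechain_mass
A	1.8	-0.5	15.0
C	2.5	-1.0	47.0
D	-3.5	3.0	59.0
E	-3.5	3.0	73.0
F	2.8	-2.5	91.0
G	-0.4	0.0	1.0
H	-3.2	-0.5	82.0
I	4.5	-1.8	57.0
K	-3.9	3.0	73.0
L	3.8	-1.8	57.0
M	1.9	-1.3	75.0
N	-3.5	0.2	58.0
P	-1.6	0.0	42.0
Q	-3.5	0.2	72.0
R	-4.5	3.0	101.0
S	-0.8	0.3	31.0
T	-0.7	-0.4	45.0
V	4.2	-1.5	43.0
W	-0.9	-3.4	130.0
Y	-1.3	-2.3	107.0
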
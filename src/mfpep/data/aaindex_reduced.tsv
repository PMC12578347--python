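# Reduced AAindex-style per-residue property table: twelve well-known
# published scales (Kyte-Doolittle hydropathy; Hopp-Woods hydrophilicity;
# side-chain mass; alpha-COOH and alpha-NH3+ pK values; isoelectric point;
# van der Waals volume (Zamyatnin); Grantham polarity; Bhaskaran-Ponnuswamy
# average flexibility; net charge at pH 7; aromatic and aliphatic
# indicators). A compact stand-in for the full 531-column AAindex matrix;
# the loader accepts any TSV with the same layout. Columns are z-scored at
# load time.
residue	hydropathy_kd	hydrophilicity_hw	sidechain_mass	pK1_cooh	pK2_nh3	pI	volume_vdw	polarity_grantham	flexibility_bp	net_charge	aromatic	aliphatic
A	1.8	-0.5	15.0	2.34	9.69	6.00	88.6	8.1	0.357	0	0	1
C	2.5	-1.0	47.0	1.96	10.28	5.07	108.5	5.5	0.346	0	0	0
D	-3.5	3.0	59.0	1.88	9.60	2.77	111.1	13.0	0.511	-1	0	0
E	-3.5	3.0	73.0	2.19	9.67	3.22	138.4	12.3	0.497	-1	0	0
F	2.8	-2.5	91.0	1.83	9.13	5.48	189.9	5.2	0.314	0	1	0
G	-0.4	0.0	1.0	2.34	9.60	5.97	60.1	9.0	0.544	0	0	0
H	-3.2	-0.5	82.0	1.82	9.17	7.59	153.2	10.4	0.323	0.1	1	0
I	4.5	-1.8	57.0	2.36	9.60	6.02	166.7	5.2	0.462	0	0	1
K	-3.9	3.0	73.0	2.18	8.95	9.74	168.6	11.3	0.466	1	0	0
L	3.8	-1.8	57.0	2.36	9.60	5.98	166.7	4.9	0.365	0	0	1
M	1.9	-1.3	75.0	2.28	9.21	5.74	162.9	5.7	0.295	0	0	0
N	-3.5	0.2	58.0	2.02	8.80	5.41	114.1	11.6	0.463	0	0	0
P	-1.6	0.0	42.0	1.99	10.60	6.30	112.7	8.0	0.509	0	0	0
Q	-3.5	0.2	72.0	2.17	9.13	5.65	143.8	10.5	0.493	0	0	0
R	-4.5	3.0	101.0	2.17	9.04	10.76	173.4	10.5	0.529	1	0	0
S	-0.8	0.3	31.0	2.21	9.15	5.68	89.0	9.2	0.507	0	0	0
T	-0.7	-0.4	45.0	2.09	9.10	5.60	116.1	8.6	0.444	0	0	0
V	4.2	-1.5	43.0	2.32	9.62	5.96	140.0	5.9	0.386	0	0	1
W	-0.9	-3.4	130.0	2.83	9.39	5.89	227.8	5.4	0.305	0	1	0
Y	-1.3	-2.3	107.0	2.20	9.11	5.66	193.6	6.2	0.420	0	1	0
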
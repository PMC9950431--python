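# per-residue physicochemical property table, v1
# mw: average residue mass (monomer - water, Da); charge: integer unit charge at pH 7
# kd_hydro: Kyte-Doolittle hydropathy; top_idp: TOP-IDP disorder propensity
# ss_potential: disulfide potential (1 for Cys)
aa	mw	charge	kd_hydro	top_idp	ss_potential
A	71.0779	0	1.8	0.06	0
C	103.1429	0	2.5	0.02	1
D	115.0874	-1	-3.5	0.192	0
E	129.114	-1	-3.5	0.736	0
F	147.1738	0	2.8	-0.697	0
G	57.0513	0	-0.4	0.166	0
H	137.1393	0	-3.2	0.303	0
I	113.1576	0	4.5	-0.486	0
K	128.1723	1	-3.9	0.586	0
L	113.1576	0	3.8	-0.326	0
M	131.196	0	1.9	-0.397	0
N	114.1026	0	-3.5	0.007	0
P	97.1152	0	-1.6	0.987	0
Q	128.1292	0	-3.5	0.318	0
R	156.1857	1	-4.5	0.18	0
S	87.0773	0	-0.8	0.341	0
T	101.1039	0	-0.7	0.059	0
V	99.131	0	4.2	-0.121	0
W	186.2099	0	-0.9	-0.884	0
Y	163.1732	0	-1.3	-0.51	0
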
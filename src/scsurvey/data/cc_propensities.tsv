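# Synthetic heptad propensity table, v1 (package-constructed; see docs/methods.md).
# Relative propensity of each residue at heptad positions a-g of a coiled coil:
# hydrophobics enriched at the a/d core, charged/polar residues at e/g (salt
# bridges) and the solvent-exposed b/c/f positions, helix breakers (P, G)
# strongly disfavoured everywhere.  X is neutral.
# residue	a	b	c	d	e	f	g
A	1.60	1.40	1.40	1.40	1.00	1.30	1.00
R	0.50	1.20	1.20	0.50	1.40	1.20	1.80
N	0.80	1.00	1.00	0.40	0.70	1.00	0.60
D	0.25	1.00	1.00	0.25	0.90	1.00	0.60
C	0.60	0.50	0.50	0.60	0.40	0.50	0.40
Q	0.80	1.50	1.50	0.80	1.80	1.50	1.60
E	0.40	1.80	1.80	0.40	2.80	1.80	2.50
G	0.15	0.30	0.30	0.15	0.20	0.30	0.20
H	0.50	0.70	0.70	0.50	0.60	0.70	0.60
I	3.50	0.60	0.60	2.50	0.50	0.60	0.50
L	5.50	1.10	1.10	6.00	0.80	1.10	0.80
K	0.60	1.70	1.70	0.60	2.00	1.70	2.40
M	2.50	0.70	0.70	2.00	0.60	0.70	0.60
F	1.40	0.50	0.50	1.20	0.40	0.50	0.40
P	0.02	0.03	0.03	0.02	0.02	0.03	0.02
S	0.40	0.90	0.90	0.40	0.70	0.90	0.70
T	0.50	0.80	0.80	0.50	0.60	0.80	0.60
W	0.40	0.40	0.40	0.40	0.30	0.40	0.30
Y	0.70	0.60	0.60	0.70	0.50	0.60	0.50
V	2.20	0.60	0.60	1.30	0.50	0.60	0.50
X	1.00	1.00	1.00	1.00	1.00	1.00	1.00
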
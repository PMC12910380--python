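# Three-component z-scale amino-acid descriptors (z1 lipophilicity,
# z2 steric bulk / polarizability, z3 polarity / charge), the first three
# principal components of the extended z-scale set derived by Sandberg,
# Eriksson, Jonsson, Sjostrom & Wold, J Med Chem 41:2481-2491 (1998).
# Scales 4-5 (electronegativity/heat of formation; electrophilicity/
# hardness) are deliberately not shipped: they explain little variance
# (13% and 6%) and are hard to interpret.
residue	z1	z2	z3
A	0.24	-2.32	0.60
C	0.84	-1.67	3.71
D	3.98	0.93	1.93
E	3.11	0.26	-0.11
F	-4.22	1.94	1.06
G	2.05	-4.06	0.36
H	2.47	1.95	0.26
I	-3.89	-1.73	-1.71
K	2.29	0.89	-2.49
L	-4.28	-1.30	-1.49
M	-2.85	-0.22	0.47
N	3.05	1.62	1.04
P	-1.66	0.27	1.84
Q	1.75	0.50	-1.44
R	3.52	2.50	-3.50
S	2.39	-1.07	1.15
T	0.75	-2.18	-1.12
V	-2.59	-2.64	-1.54
W	-4.36	3.94	0.59
Y	-2.54	2.44	0.43
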
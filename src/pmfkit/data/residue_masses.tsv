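# Amino-acid residue masses in Da.
# mono: monoisotopic (lightest-isotope) residue mass
# avg: average residue mass (isotope-abundance weighted, ProtParam convention)
residue	mono	avg
A	71.037114	71.0788
C	103.009185	103.1388
D	115.026943	115.0886
E	129.042593	129.1155
F	147.068414	147.1766
G	57.021464	57.0519
H	137.058912	137.1411
I	113.084064	113.1594
K	128.094963	128.1741
L	113.084064	113.1594
M	131.040485	131.1926
N	114.042927	114.1038
P	97.052764	97.1167
Q	128.058578	128.1307
R	156.101111	156.1875
S	87.032028	87.0782
T	101.047678	101.1051
V	99.068414	99.1326
W	186.079313	186.2132
Y	163.063329	163.1760
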
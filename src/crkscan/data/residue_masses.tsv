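# Average masses of the free amino acids (Da); peptide mass is the sum
# minus one water per peptide bond.
A	89.0935
R	174.2017
N	132.1184
D	133.1032
C	121.1590
E	147.1293
Q	146.1451
G	75.0669
H	155.1552
I	131.1736
L	131.1736
K	146.1882
M	149.2124
F	165.1900
P	115.1310
S	105.0930
T	119.1197
W	204.2262
Y	181.1894
V	117.1469
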
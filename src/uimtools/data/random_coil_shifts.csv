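# Random-coil backbone chemical shifts (ppm), one row per amino acid.
# Values are standard literature-style random-coil references for
# unstructured peptides; glycine has no beta carbon (empty CB field).
residue,CA,CB,C,N,H,HA
A,52.5,19.1,177.8,123.8,8.24,4.32
C,58.2,28.0,174.6,118.8,8.32,4.55
D,54.2,41.1,176.3,120.4,8.34,4.64
E,56.6,29.9,176.6,120.2,8.42,4.35
F,57.7,39.6,175.8,120.3,8.30,4.62
G,45.1,,174.9,108.8,8.33,3.96
H,55.0,29.0,174.1,118.2,8.42,4.73
I,61.1,38.8,176.4,119.9,8.00,4.17
K,56.2,33.1,176.6,120.4,8.29,4.32
L,55.1,42.4,177.6,121.8,8.16,4.34
M,55.4,32.9,176.3,119.6,8.28,4.48
N,53.1,38.9,175.2,118.7,8.40,4.74
P,63.3,32.1,177.3,,,4.42
Q,55.7,29.4,176.0,119.8,8.32,4.34
R,56.0,30.9,176.3,120.5,8.23,4.34
S,58.3,63.8,174.6,115.7,8.31,4.47
T,61.8,69.8,174.7,113.6,8.15,4.35
V,62.2,32.9,176.3,119.2,8.03,4.12
W,57.5,29.6,176.1,121.3,8.25,4.66
Y,57.9,38.8,175.9,120.3,8.12,4.55
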
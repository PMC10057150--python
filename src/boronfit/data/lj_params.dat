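# 12-6 Lennard-Jones parameters per atom type: type  R* (Å)  epsilon (kcal/mol)
# GAFF-like values for the organic types; the boron entry is this package's
# own choice (tetrahedral boronate boron, shallow well) — see docs/methods.md.
b    2.0000  0.0500
o    1.6837  0.1700
oh   1.7210  0.2104
ho   0.6000  0.0157
c2   1.9080  0.0860
c3   1.9080  0.1094
ca   1.9080  0.0860
ha   1.4590  0.0150
h1   1.3870  0.0157
hc   1.4870  0.0157
n3   1.8240  0.1700
hn   0.6000  0.0157
2c   1.9080  0.1094
cx   1.9080  0.1094
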
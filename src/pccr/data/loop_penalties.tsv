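# Destabilizing free energies (kcal/mol, 37 C) of the short bulges and internal
# loops admitted between two helices: up to m=2 unpaired nucleotides per strand.
# Generic Turner-2004 initiation terms: bulge initiation for (n,0); internal
# loop initiation by total size plus 0.6 kcal/mol per unit of asymmetry for
# (n1,n2) with n1,n2 >= 1. Sequence-independent by design. Symmetric in (n1,n2).
n1	n2	penalty
0	1	3.80
0	2	2.80
1	1	1.00
1	2	1.60
2	2	1.10
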
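# Nearest-neighbor helix stacking free energies, RNA, 37 C (kcal/mol).
# Turner 2004 parameter set. Each row is one dinucleotide step written as
# top strand 5'->3' over bottom strand 3'->5'; base pairs are column-wise.
# Watson-Crick steps carry the published two-decimal values; wobble-containing
# steps carry the Vienna RNA (rna_turner2004) values at 0.1 kcal precision.
# The loader expands each step to its symmetric counterpart (read in the
# opposite direction) and checks consistency.
top	bottom	dg
AA	UU	-0.93
AU	UA	-1.10
UA	AU	-1.33
CU	GA	-2.08
CA	GU	-2.11
GU	CA	-2.24
GA	CU	-2.35
CG	GC	-2.36
GG	CC	-3.26
GC	CG	-3.42
GG	UU	-0.50
GU	UG	1.30
UG	GU	0.30
GA	UU	-1.30
GC	UG	-2.50
GG	UC	-2.10
GU	UA	-1.40
AG	UU	-0.60
CG	GU	-1.40
GG	CU	-1.50
UG	AU	-1.00
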
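# RNA/RNA Watson-Crick nearest-neighbor stack free energies at 37 C, kcal/mol.
# Values from the standard Xia et al. (1998) Watson-Crick parameter set,
# expanded to all 16 top-strand dinucleotides via rotational equivalence
# (5'XY3'/3'WZ5' == 5'comp(Y)comp(X)3'/...).
# Schema: one stack per row ("XY/WZ" <tab> energy), plus named rows
# "init" (duplex initiation) and "terminal_au" (per AU/UA terminal pair),
# and a "source" tag row.
source	xia1998-wc-37C
AA/UU	-0.93
AC/UG	-2.24
AG/UC	-2.08
AU/UA	-1.10
CA/GU	-2.11
CC/GG	-3.26
CG/GC	-2.36
CU/GA	-2.08
GA/CU	-2.35
GC/CG	-3.42
GG/CC	-3.26
GU/CA	-2.24
UA/AU	-1.33
UC/AG	-2.35
UG/AC	-2.11
UU/AA	-0.93
init	4.09
terminal_au	0.45
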
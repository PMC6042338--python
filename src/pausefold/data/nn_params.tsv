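# DNA nearest-neighbor thermodynamic parameters (unified oligonucleotide set)
# and single-stranded loop penalties used by the builtin folding engine.
#
# stack rows:  kind=stack  key=5'XY3' (top strand of the duplex step)
#              dh in kcal/mol, ds in cal/(mol*K), at 1 M NaCl reference.
#              The 6 missing steps follow by reverse-complement symmetry.
# loop rows:   kind in {hairpin, bulge, internal}  key=loop size (nt),
#              dg37 in kcal/mol at 37 C; intermediate sizes are linearly
#              interpolated, sizes beyond the largest entry extrapolated
#              with a Jacobson-Stockmayer log term.
kind	key	dh	ds	dg37
stack	AA	-7.9	-22.2	.
stack	AT	-7.2	-20.4	.
stack	TA	-7.2	-21.3	.
stack	CA	-8.5	-22.7	.
stack	GT	-8.4	-22.4	.
stack	CT	-7.8	-21.0	.
stack	GA	-8.2	-22.2	.
stack	CG	-10.6	-27.2	.
stack	GC	-9.8	-24.4	.
stack	GG	-8.0	-19.9	.
hairpin	3	.	.	3.5
hairpin	4	.	.	3.5
hairpin	5	.	.	3.3
hairpin	6	.	.	4.0
hairpin	7	.	.	4.3
hairpin	8	.	.	4.3
hairpin	9	.	.	4.5
hairpin	10	.	.	4.5
hairpin	12	.	.	5.0
hairpin	14	.	.	5.1
hairpin	16	.	.	5.3
hairpin	18	.	.	5.5
hairpin	20	.	.	5.7
hairpin	25	.	.	6.1
hairpin	30	.	.	6.3
bulge	1	.	.	4.0
bulge	2	.	.	2.9
bulge	3	.	.	3.1
bulge	4	.	.	3.2
bulge	5	.	.	3.3
bulge	6	.	.	3.5
bulge	7	.	.	3.7
bulge	8	.	.	3.9
bulge	9	.	.	4.1
bulge	10	.	.	4.3
bulge	12	.	.	4.5
bulge	14	.	.	4.8
bulge	16	.	.	5.0
bulge	18	.	.	5.2
bulge	20	.	.	5.3
bulge	25	.	.	5.6
bulge	30	.	.	5.9
internal	2	.	.	2.3
internal	3	.	.	3.2
internal	4	.	.	3.6
internal	5	.	.	4.0
internal	6	.	.	4.4
internal	7	.	.	4.6
internal	8	.	.	4.8
internal	9	.	.	4.9
internal	10	.	.	4.9
internal	12	.	.	5.2
internal	14	.	.	5.4
internal	16	.	.	5.6
internal	18	.	.	5.8
internal	20	.	.	5.9
internal	25	.	.	6.3
internal	30	.	.	6.6
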
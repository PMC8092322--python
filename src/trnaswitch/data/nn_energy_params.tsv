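# Nearest-neighbor free-energy parameters for RNA secondary structure.
# Turner-style magnitudes; dH in kcal/mol, dG37 in kcal/mol at 310.15 K.
# dS (kcal/mol/K) is derived at load time as (dH - dG37) / 310.15.
# stack keys "AB/CD": 5'-A B-3' / 3'-D C-5' with pairs A:D and B:C,
# canonicalized as min(key, reverse-strand reading).  Watson-Crick entries
# follow published magnitudes; G.U-containing stacks carry representative
# values (one G.U: -1.40; two G.U: -0.50), since only sign and ordering are
# contractual for this model.
# loop keys are loop sizes (unpaired nucleotides); loops are modeled as
# purely entropic (dH = 0).  multibranch keys: a (closing penalty),
# b (per branch), c (per unpaired nucleotide).
# kind	key	dH	dG37
stack	AA/UU	-6.82	-0.93
stack	AC/GU	-11.40	-2.24
stack	AG/CU	-10.48	-2.08
stack	AG/UU	-9.00	-1.40
stack	AU/AU	-9.38	-1.10
stack	AU/GU	-9.00	-1.40
stack	CA/UG	-10.44	-2.11
stack	CC/GG	-13.39	-3.26
stack	CG/CG	-10.64	-2.36
stack	CG/UG	-9.00	-1.40
stack	CU/GG	-9.00	-1.40
stack	GA/UC	-12.44	-2.35
stack	GA/UU	-9.00	-1.40
stack	GC/GC	-14.88	-3.42
stack	GC/GU	-9.00	-1.40
stack	GG/UC	-9.00	-1.40
stack	GG/UU	-7.00	-0.50
stack	GU/GU	-7.00	-0.50
stack	UA/UA	-7.69	-1.33
stack	UA/UG	-9.00	-1.40
stack	UG/UG	-7.00	-0.50
hairpin	3	0.00	5.40
hairpin	4	0.00	5.60
hairpin	5	0.00	5.70
hairpin	6	0.00	5.40
hairpin	7	0.00	6.00
hairpin	8	0.00	5.50
hairpin	9	0.00	6.40
bulge	1	0.00	3.80
bulge	2	0.00	2.80
bulge	3	0.00	3.20
bulge	4	0.00	3.60
bulge	5	0.00	4.00
bulge	6	0.00	4.40
internal	2	0.00	1.50
internal	3	0.00	1.80
internal	4	0.00	1.70
internal	5	0.00	2.00
internal	6	0.00	2.20
internal	7	0.00	2.30
internal	8	0.00	2.50
multibranch	a	0.00	3.40
multibranch	b	0.00	0.40
multibranch	c	0.00	0.10
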
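# spanfold nearest-neighbour energy parameters, kcal/mol at 37 C
# STACK <outer pair> <inner pair> <dG>   (outer pair (a,b), inner pair (a+1,b-1))
# HAIRPIN/BULGE/INTERNAL <loop size> <dG>; sizes beyond the table are
# extrapolated with dG(max) + jacobson * ln(n / max).
# Turner-like default values; symmetric under (P,Q) -> (rev Q, rev P).
STACK	AU	AU	-0.93
STACK	UA	UA	-0.93
STACK	AU	UA	-1.10
STACK	UA	AU	-1.33
STACK	AU	CG	-2.24
STACK	GC	UA	-2.24
STACK	AU	GC	-2.08
STACK	CG	UA	-2.08
STACK	AU	GU	-0.55
STACK	UG	UA	-0.55
STACK	AU	UG	-1.36
STACK	GU	UA	-1.36
STACK	UA	CG	-2.35
STACK	GC	AU	-2.35
STACK	UA	GC	-2.11
STACK	CG	AU	-2.11
STACK	UA	GU	-1.27
STACK	UG	AU	-1.27
STACK	UA	UG	-1.00
STACK	GU	AU	-1.00
STACK	CG	CG	-3.26
STACK	GC	GC	-3.26
STACK	CG	GC	-2.36
STACK	GC	CG	-3.42
STACK	CG	GU	-1.41
STACK	UG	GC	-1.41
STACK	CG	UG	-2.11
STACK	GU	GC	-2.11
STACK	GC	GU	-1.53
STACK	UG	CG	-1.53
STACK	GC	UG	-2.51
STACK	GU	CG	-2.51
STACK	GU	GU	-0.50
STACK	UG	UG	-0.50
STACK	GU	UG	1.29
STACK	UG	GU	0.30
HAIRPIN	3	5.40
HAIRPIN	4	5.60
HAIRPIN	5	5.70
HAIRPIN	6	5.40
HAIRPIN	7	6.00
HAIRPIN	8	5.50
HAIRPIN	9	6.40
BULGE	1	3.80
BULGE	2	2.80
BULGE	3	3.20
BULGE	4	3.60
BULGE	5	4.00
BULGE	6	4.40
INTERNAL	2	1.00
INTERNAL	3	1.40
INTERNAL	4	1.70
INTERNAL	5	1.80
INTERNAL	6	2.00
MULTI	closing	3.40
MULTI	branch	0.40
MULTI	unpaired	0.00
TERMINAL_AU	0.50
JACOBSON	1.08
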
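# Strand-bias mispair counts of 5-FOA-resistant mutants from the
# polδ-L591M fission-yeast strains carrying the ura4+:ura5+ reporter in the
# forward and reverse orientations, attributed under the
# transcribed-strand-synthesis hypothesis (forward column = lagging-strand
# synthesis of the transcribed strand, reverse column = leading).
# hypothesis: transcribed-strand synthesis
# orientation_role: forward=lagging,reverse=leading
# mclass	mispair	orientation	count
AT>GC	A:dC	forward	2
AT>GC	T:dG	forward	25
AT>GC	A:dC	reverse	10
AT>GC	T:dG	reverse	4
GC>AT	G:dT	forward	15
GC>AT	C:dA	forward	5
GC>AT	G:dT	reverse	8
GC>AT	C:dA	reverse	27
GC>TA	G:dA	forward	9
GC>TA	C:dT	forward	4
GC>TA	G:dA	reverse	31
GC>TA	C:dT	reverse	3
AT>TA	A:dA	forward	4
AT>TA	T:dT	forward	1
AT>TA	A:dA	reverse	7
AT>TA	T:dT	reverse	3
AT>CG	A:dG	forward	0
AT>CG	T:dC	forward	4
AT>CG	A:dG	reverse	4
AT>CG	T:dC	reverse	0
GC>CG	G:dG	forward	2
GC>CG	C:dC	forward	0
GC>CG	G:dG	reverse	0
GC>CG	C:dC	reverse	0
ΔAT	ΔA	forward	9
ΔAT	ΔT	forward	23
ΔAT	ΔA	reverse	10
ΔAT	ΔT	reverse	13
ΔGC	ΔG	forward	11
ΔGC	ΔC	forward	8
ΔGC	ΔG	reverse	7
ΔGC	ΔC	reverse	7
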
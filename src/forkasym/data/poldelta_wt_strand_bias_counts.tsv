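# Strand-bias mispair counts of 5-FOA-resistant mutants from the polδ+
# control strains (ura4+:ura5+ reporter, forward and reverse orientations),
# attributed under the transcribed-strand-synthesis hypothesis.  No
# significant strand bias is present in these counts.
# hypothesis: transcribed-strand synthesis
# orientation_role: forward=lagging,reverse=leading
# mclass	mispair	orientation	count
AT>GC	A:dC	forward	1
AT>GC	T:dG	forward	0
AT>GC	A:dC	reverse	3
AT>GC	T:dG	reverse	5
GC>AT	G:dT	forward	13
GC>AT	C:dA	forward	10
GC>AT	G:dT	reverse	22
GC>AT	C:dA	reverse	17
GC>TA	G:dA	forward	20
GC>TA	C:dT	forward	12
GC>TA	G:dA	reverse	29
GC>TA	C:dT	reverse	6
AT>TA	A:dA	forward	4
AT>TA	T:dT	forward	3
AT>TA	A:dA	reverse	2
AT>TA	T:dT	reverse	3
AT>CG	A:dG	forward	1
AT>CG	T:dC	forward	7
AT>CG	A:dG	reverse	2
AT>CG	T:dC	reverse	5
GC>CG	G:dG	forward	0
GC>CG	C:dC	forward	1
GC>CG	G:dG	reverse	0
GC>CG	C:dC	reverse	4
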
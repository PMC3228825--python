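# Relative in-vitro error rates per template:dNTP mispair for the
# budding-yeast polδ L612M mutant (ortholog of fission-yeast polδ L591M),
# used as the default prior for strand assignment.  Values are approximate
# transcriptions of the published in-vitro expectations and are meant to be
# edited by the user; only within-pair ratios matter.
# source: Polδ L612M in vitro error spectrum (approximate relative rates)
# mispair	relative_rate
A:dC	1
T:dG	18
G:dT	2
C:dA	1
G:dA	7
C:dT	14
A:dA	2
T:dT	12
ΔA	1
ΔT	5
ΔG	17
ΔC	1
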
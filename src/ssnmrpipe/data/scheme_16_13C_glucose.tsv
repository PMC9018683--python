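# 1,6-13C-glucose sparse labeling pattern (literature-derived approximation,
# user-overridable).  Enrichment at methyl/side-chain positions via pyruvate
# C3; CA largely unlabeled.
# nitrogen_labeled: true
residue_type	atom_name	fraction
*	CB	0.7
*	CG	0.5
*	CG1	0.5
*	CG2	0.5
*	CD	0.5
*	CD1	0.5
*	CD2	0.5
*	CE	0.5
*	C	0.3
*	CA	0.05
*	*	0.1
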
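# 2-13C-glucose sparse labeling pattern (literature-derived approximation,
# user-overridable).  Dominant enrichment at CA positions via pyruvate C2;
# carbonyl and side-chain carbons largely unlabeled.
# nitrogen_labeled: true
residue_type	atom_name	fraction
*	CA	0.85
*	C	0.05
*	CB	0.05
*	CG	0.05
*	CG1	0.05
*	CG2	0.05
*	CD	0.05
*	CD1	0.05
*	CD2	0.05
*	CE	0.05
*	CE1	0.05
*	CE2	0.05
*	CZ	0.05
*	*	0.05
LEU	CA	0.4
VAL	CA	0.4
ILE	CA	0.4
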
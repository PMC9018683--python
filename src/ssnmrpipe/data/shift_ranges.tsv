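# Average chemical-shift centers and spreads per atom type (ppm), used to
# draw synthetic shift tables with realistic degeneracy.
atom_name	mean_ppm	sd_ppm
C	175.5	1.8
CA	58.0	3.5
CB	33.0	7.0
N	119.5	4.5
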
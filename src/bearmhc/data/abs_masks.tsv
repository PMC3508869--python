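# Antigen-binding-site (ABS) codon masks, 1-based codon indices within
# each marker's second-exon alignment fragment.
#
# SYNTHETIC RECONSTRUCTIONS: these positions are re-derived from the HLA
# structural consensus (pocket residues of HLA-A/B/C for class I, of
# HLA-DRbeta / DQalpha / DQbeta for class II, after Reche & Reinherz 2003)
# mapped onto the fragment coordinates, not taken from any species-specific
# annotation. Edit freely; every analysis takes the mask as an input.
#
# marker<TAB>space-separated codon indices
U	6 8 22 44 46 48 50 52 56 58 61 62 65 68 72 73 75 76
DRB	4 6 9 21 23 25 32 36 42 50 53 55 58 63 66 69
DQA	8 13 29 34 40 45 50 55 58 61 64 67
DQB	7 11 17 26 29 35 45 53 56 59 62 65 68 71
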
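# Default archaeal single-copy gene family manifest (38 families).
# Placeholder family ids with the canonical set size; user-replaceable.
ar_rpL2
ar_rpL3
ar_rpL4
ar_rpL5
ar_rpL6
ar_rpL10
ar_rpL11
ar_rpL13
ar_rpL14
ar_rpL15
ar_rpL18
ar_rpL22
ar_rpL23
ar_rpL24
ar_rpL29
ar_rpL30
ar_rpS2
ar_rpS3
ar_rpS4
ar_rpS5
ar_rpS7
ar_rpS8
ar_rpS9
ar_rpS10
ar_rpS11
ar_rpS12
ar_rpS13
ar_rpS15
ar_rpS17
ar_rpS19
ar_eif2a
ar_eif5a
ar_secY
ar_ffh
ar_prf1
ar_rpoA
ar_rpoB
ar_psmA
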
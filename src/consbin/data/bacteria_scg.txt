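# Default bacterial single-copy gene family manifest (51 families).
# Placeholder family ids with the canonical set size; replace with your own
# manifest (one family id per line) to match your homology-search database.
rpL1
rpL2
rpL3
rpL4
rpL5
rpL6
rpL9
rpL10
rpL11
rpL13
rpL14
rpL15
rpL16
rpL17
rpL18
rpL19
rpL20
rpL21
rpL22
rpL23
rpL24
rpL27
rpL28
rpL29
rpS2
rpS3
rpS4
rpS5
rpS6
rpS7
rpS8
rpS9
rpS10
rpS11
rpS12
rpS13
rpS15
rpS16
rpS17
rpS18
rpS19
rpS20
tsf
rpoB
recA
gyrA
smpB
rnc
dnaG
nusA
ftsY
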
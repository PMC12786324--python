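# Default circadian cis-element families (IUPAC alternatives are OR-ed).
# Pdp1 and PER-repeat alternatives are reverse complements of each other,
# so those families match identically in either orientation.
Ebox_canonical: [CACGTG]
Ebox_degenerate: [CANNTG]
Dbox: [TTATGYAA]
CRE: [TGACGTCA]
Pdp1: [ATTTAT, ATAAAT]
PER_repeat: [CATAC, GTATG]
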
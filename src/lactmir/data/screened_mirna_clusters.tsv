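# The 25 differentially expressed miRNAs retained by the expression screen,
# with their published expression-pattern cluster (A: rising across stages,
# B: dip at peak, C: peak ~ late > early, D: maximum at peak,
# E: peak ~ late < early).
miRNA	cluster
bta-miR-29b	A
bta-miR-29c	A
bta-miR-375	A
bta-miR-135a	A
bta-miR-22-5p	A
bta-miR-885	A
bta-miR-214	A
bta-miR-33a	A
bta-miR-451	A
bta-miR-190a	A
bta-miR-378	B
bta-miR-423-5p	B
bta-miR-7	B
bta-miR-22-3p	C
bta-miR-99a	C
bta-miR-185	C
bta-miR-1	D
bta-miR-2284x	D
bta-miR-125a	D
bta-miR-382	D
bta-miR-423-3p	D
bta-miR-660	D
bta-miR-100	D
bta-miR-146a	E
bta-miR-184	E
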
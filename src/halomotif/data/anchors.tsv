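# Degenerate anchor patterns for the ten functional sites ('x' = any residue;
# character classes follow regex syntax).  Trp1-4 patterns are derived from
# the characterized-halogenase motif catalogue; FAD2-4 and the catalytic-K
# anchors are permissive package defaults meant to be edited for a new family.
FAD1	GxGxxG
FAD2	[DE]x[LIVM][LIVM][LIVM]G
Trp1	AT[IVF][PS]xx
Trp2	[HQY][LPS]F[GE]x
Trp3	QxxQ
Trp3	QxxxQ
K	[FWY]K[GSTA]
FAD3	DS[LIVM]FxG
FAD4	F[LIVM]EYS[RK]
halide	WxWxIP
Trp4	YYxxF[ED][AYVEF]EF[RK]NFWxN[GSA][NS]YY
Trp4	[YHF]YHG[LF][PE]xYS
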
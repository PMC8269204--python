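# The 13 experimentally validated tryptophan halogenases used as pHMM seeds.
enzyme	accession
AbeH	AEF32095.1
ClaH	AEO12707.1
PyrH	AAU95674.1
KtzR	ABV56598.1
SttH	ADW94630.1
Th-Hal	WP_023586065.1
ThdH	ABK79936.1
BorH	AGI62217.1
FmoD	BAP16687.1
AORI_5336	AGM07919.1
KtzQ	ABV56597.1
PrnA	AAB97504.1
RebH	CAC93722.1
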
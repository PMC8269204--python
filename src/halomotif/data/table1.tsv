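# Experimentally characterized flavin-dependent halogenases: cluster, observed
# regioselectivity toward tryptophan, and Trp1-4 motif strings ('-' = absent).
group	enzyme	regioselectivity	trp1	trp2	trp3	trp4
A1	PrnA	7	ATIPSL	HLFGN	-	YYETFDFEFKNFWLNGNYY
A1	Hal1	7	ATIPSL	HLFGN	-	YYETFDFEFKNFWLNGNYY
A1	KtzQ	7	ATIPNL	HLFGQ	-	YYGNFEAEFRNFWTNSNYY
A1	RebH	7	ATIPNL	HSFGL	-	YYGNFEEEFRNFWNNSNYY
A1	Hal7	7	ATIPNL	HLFGL	-	YYGNFEAEFRNFWSNANYY
A2	ThdH	6	ATVPNL	HPFGL	-	YYGNFEAEFRNFWTNGSYY
A2	FmoD	6	ATVPNL	HPFGL	-	YYGNFEAEFRNFWTNGSYY
A2	Hal3	6	ATIPNL	HPFGL	-	YYGNFEAEFRNFWTNGSYY
A2	BorH	6	ATVPNL	HPFGL	-	YYGRFEAEFRNFWTNGSYY
A2	AORI_5336	6	ATVPNL	HPFGL	-	YYGNFDAEFRNFWTNGSYY
A2	Hal2	6	ATVPNL	HPFGL	-	YYDNFDVEFRNFWTNGSYY
B2	Th-Hal	6	ATFSDI	HPFEQ	QGKTQ	YYHGLPPYS
B2	KtzR	6	ATFSDI	QPFEQ	QGKSQ	YYHGLPPYS
B2	SttH	6	ATFSDI	HPFEQ	QGKTQ	YYHGLPPYS
B2	Tar14	6	ATFSDI	HPFEQ	QGAQ	YYHGLPPYS
B2	Hal4	6	ATFSDI	HPFEQ	QGKTQ	YYHGLPAYS
B2	Hal5	6	ATFSDI	HPFEQ	QGTQ	HYHGLPPYS
B1	ClaH	5	ATFSTV	HPFER	QGTQ	HYHGFEAYS
B1	AbeH	5	ATFSTV	HPFER	QTTQ	HYHGFESYS
B1	PyrH	5	ATFSTV	HPFER	QRAQ	YYHGFETYS
B1	SpmH	5	ATFSTV	HPFER	QRAQ	YYHGFEPYS
B1	XszenFHal	5	ATFSTV	HPFER	QRAQ	FYHGFEEYS
B1	Hal6	5	ATFSTV	HPFER	QRAQ	YYHGFESYS
C	KrmI	6	ATTPSL	YPFGA	-	-
C	MibH	NA	ATVSYM	APFDW	-	-
C	BrvH	NA	ATIPTI	HPFGL	-	-
C	VirX1	NA	STLGHF	YPFGP	-	-
C	Xcc-b100-1333	NA	STVPPI	HPFGS	-	-
C	Xcc-b100-4156	NA	ATIPSL	HSFGH	-	-
C	Xcc-b100-4345	NA	ATVPHI	HGFGT	-	-
C	MHal1	NA	ATMPNI	HSFDS	-	-
C	MHal2	NA	ATIIQM	NPFQP	-	-
C	MHal3	NA	ATVPGM	HPFNS	-	-
C	MHal4	NA	ATIPPL	HSFGD	-	-
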
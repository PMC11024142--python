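source_label	cupid_class	excluded	reason
ACC	ACC	0
BLCA	BLCA	0
BRCA	BRCA	0
CESC_squamous	CervSq	0
CESC_adenocarcinoma	Gynae	0
CESC_adenosquamous	-	1	mixed histology
CHOL	CHOL	0
GSE32079	CHOL	0
GSE49656	CHOL	0
GSE89803	CHOL	0
DLBC	DLBC	0
GBM	GBM	0
OV	Gynae	0
UCEC	Gynae	0
UCS	Gynae	0
KICH	KICH	0
KIRC	KIRC	0
KIRP	KIRP	0
LAML	LAML	0
LGG	LGG	0
LIHC	LIHC	0
LIHC_hepatocholangiocarcinoma_mixed	-	1	mixed histology
LIHC_adjacent_normal	NCC	0
COAD	LowerGI	0
READ	LowerGI	0
LUAD	LUAD	0
LUSC	LUSC	0
MESO	MESO	0
PAAD	PAAD	0
PCPG	PCPG	0
PRAD	PRAD	0
SARC	SARC	0
SKCM	SKCM	0
TGCT	TGCT	0
THCA	THCA	0
THYM	THYM	0
ESCA_adenocarcinoma	UpperGI	0
ESCA_squamous	UpperSq	0
STAD	UpperGI	0
HNSC	UpperSq	0
UVM	UVM	0
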
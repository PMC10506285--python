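CSC_SIGNATURE	Published cancer stem cell marker genes for hepatocellular carcinoma	SP	PROM1	ALDH1A1	THY1	EPCAM	ANPEP	CD44	CD24	CXCL12	ICAM1	CACNA2D1	CD47	LGR5	KRT19	ABCG2	AFP	SOX9	POU5F1	SOX2	NANOG	NOTCH	ZIC2	PBX3	ZNF148	TCIM	SALL4	ZFP42	YY1A1	FOXM1	MYCN	SCD	MRPS5	PMPCB	ANGPTL4	PDK4	XDH	IRAK1	PTPN11	ANXA3	IL6	IL8	OSM	IGF1	FGF2	ANGPTL1	CTSS	UBE2T	EPHB2
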
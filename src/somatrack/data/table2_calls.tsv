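# Recurrent-variant presence calls per specimen; af_percent 0-100.
# Cells without a printed allele fraction carry a nominal 50.0.
specimen_id	gene	hgvs_p	consequence	af_percent
c01_PT	KRAS	p.G12D	missense	55.59
c01_synHEP_1	KRAS	p.G12D	missense	97.28
c01_metPUL_1	KRAS	p.G12D	missense	16.77
c01_PT	TP53	p.R342*	nonsense	50.0
c01_metPUL_1	TP53	p.R342*	nonsense	50.0
c02_PT	APC	p.Q1338*	nonsense	50.0
c02_synHEP_1	APC	p.Q1338*	nonsense	50.0
c02_synPUL_1	APC	p.Q1338*	nonsense	50.0
c02_synPUL_2	APC	p.Q1338*	nonsense	50.0
c02_PT	KRAS	p.G12V	missense	53.59
c02_synHEP_1	KRAS	p.G12V	missense	89.98
c02_synPUL_1	KRAS	p.G12V	missense	47.32
c02_synPUL_2	KRAS	p.G12V	missense	32.82
c02_PT	SMAD4	p.R361C	missense	50.0
c02_synHEP_1	SMAD4	p.R361C	missense	50.0
c02_synPUL_1	SMAD4	p.R361C	missense	50.0
c02_synPUL_2	SMAD4	p.R361C	missense	50.0
c03_metHEP_1	APC	p.R1450*	nonsense	50.0
c03_metPUL_1	APC	p.R1450*	nonsense	50.0
c03_metPUL_3	APC	p.R1450*	nonsense	50.0
c03_PT	APC	p.R876*	nonsense	50.0
c03_metHEP_1	APC	p.R876*	nonsense	50.0
c03_metPUL_1	APC	p.R876*	nonsense	50.0
c03_metPUL_2	APC	p.R876*	nonsense	50.0
c03_metPUL_3	APC	p.R876*	nonsense	50.0
c03_PT	KRAS	p.G12V	missense	21.92
c03_metHEP_1	KRAS	p.G12V	missense	45.26
c03_metPUL_2	KRAS	p.G12V	missense	21.22
c03_metPUL_3	KRAS	p.G12V	missense	34.0
c03_metHEP_1	PIK3CA	p.K111E	missense	50.0
c03_metPUL_3	PIK3CA	p.K111E	missense	50.0
c03_PT	TP53	p.R196*	nonsense	50.0
c03_metHEP_1	TP53	p.R196*	nonsense	50.0
c03_metPUL_1	TP53	p.R196*	nonsense	50.0
c03_metPUL_2	TP53	p.R196*	nonsense	50.0
c03_metPUL_3	TP53	p.R196*	nonsense	50.0
c04_PT	TP53	p.R337C	missense	50.0
c04_synHEP_1	TP53	p.R337C	missense	50.0
c04_metHEP_1	TP53	p.R337C	missense	50.0
c04_metPUL_1	TP53	p.R337C	missense	50.0
c04_PT	TP53	p.G199V	missense	50.0
c04_synHEP_1	TP53	p.G199V	missense	50.0
c04_metHEP_1	TP53	p.G199V	missense	50.0
c04_metPUL_1	TP53	p.G199V	missense	50.0
c05_PT	APC	p.P1319Lfs*	frameshift	50.0
c05_synHEP_1	APC	p.P1319Lfs*	frameshift	50.0
c05_synPUL_1	APC	p.P1319Lfs*	frameshift	50.0
c05_synPUL_2	APC	p.P1319Lfs*	frameshift	50.0
c05_PT	KRAS	p.G12A	missense	24.18
c05_synHEP_1	KRAS	p.G12A	missense	9.7
c05_synPUL_1	KRAS	p.G12A	missense	17.72
c05_synPUL_2	KRAS	p.G12A	missense	36.04
c05_PT	PIK3CA	p.E542K	missense	50.0
c05_synHEP_1	PIK3CA	p.E542K	missense	50.0
c05_synPUL_1	PIK3CA	p.E542K	missense	50.0
c05_synPUL_2	PIK3CA	p.E542K	missense	50.0
c05_PT	TP53	p.G244C	missense	50.0
c05_synHEP_1	TP53	p.G244C	missense	50.0
c05_synPUL_1	TP53	p.G244C	missense	50.0
c05_synPUL_2	TP53	p.G244C	missense	50.0
c06_PT	APC	p.Q1367*	nonsense	50.0
c06_metPUL_1	APC	p.Q1367*	nonsense	50.0
c06_PT	KRAS	p.G12V	missense	22.85
c06_metPUL_1	KRAS	p.G12V	missense	26.73
c06_PT	SMAD4	p.Q250*	nonsense	50.0
c06_metPUL_1	SMAD4	p.Q250*	nonsense	50.0
c07_PT	TP53	p.V157F	missense	50.0
c07_synHEP_1	TP53	p.V157F	missense	50.0
c07_metHEP_1	TP53	p.V157F	missense	50.0
c07_metHEP_2	TP53	p.V157F	missense	50.0
c07_metPUL_1	TP53	p.V157F	missense	50.0
c08_PT	KRAS	p.G13D	missense	34.16
c08_synHEP_1	KRAS	p.G13D	missense	50.44
c08_synPUL_1	KRAS	p.G13D	missense	31.43
c08_metPUL_1	KRAS	p.G13D	missense	12.85
c08_PT	TP53	p.R248Q	missense	50.0
c08_synHEP_1	TP53	p.R248Q	missense	50.0
c08_synPUL_1	TP53	p.R248Q	missense	50.0
c08_metPUL_1	TP53	p.R248Q	missense	50.0
c09_PT	APC	p.R1114*	nonsense	50.0
c09_synHEP_1	APC	p.R1114*	nonsense	50.0
c09_metPUL_1	APC	p.R1114*	nonsense	50.0
c09_metPUL_2	APC	p.R1114*	nonsense	50.0
c09_metPUL_3	APC	p.R1114*	nonsense	50.0
c09_PT	TP53	p.R282W	missense	50.0
c09_synHEP_1	TP53	p.R282W	missense	50.0
c09_metPUL_1	TP53	p.R282W	missense	50.0
c09_metPUL_2	TP53	p.R282W	missense	50.0
c09_metPUL_3	TP53	p.R282W	missense	50.0
c10_PT	APC	p.T1556Nfs*	frameshift	50.0
c10_metHEP_1	APC	p.T1556Nfs*	frameshift	50.0
c10_metPUL_1	APC	p.T1556Nfs*	frameshift	50.0
c10_PT	FGFR3	p.P718S	missense	50.0
c10_metPUL_1	FGFR3	p.P718S	missense	50.0
c10_metHEP_1	FGFR3	p.P718H	missense	50.0
c10_PT	TP53	p.V157G	missense	50.0
c10_metHEP_1	TP53	p.V157G	missense	50.0
c10_metPUL_1	TP53	p.V157G	missense	50.0
c11_PT	TP53	p.R273C	missense	50.0
c11_synHEP_1	TP53	p.R273C	missense	50.0
c11_metPUL_1	TP53	p.R273C	missense	50.0
c11_metPUL_2	TP53	p.R273C	missense	50.0
c12_synHEP_1	APC	p.L1488Tfs*	frameshift	50.0
c12_metPUL_1	APC	p.L1488Tfs*	frameshift	50.0
c12_metPUL_2	APC	p.L1488Tfs*	frameshift	50.0
c12_PT	KRAS	p.G12A	missense	99.74
c12_synHEP_1	KRAS	p.G12A	missense	56.72
c12_metPUL_1	KRAS	p.G12A	missense	34.15
c12_metPUL_2	KRAS	p.G12A	missense	19.63
c13_synPUL_1	ABL1	p.P315S	missense	50.0
c13_synPUL_2	ABL1	p.P315S	missense	50.0
c13_PT	APC	p.R876*	nonsense	50.0
c13_synPUL_1	APC	p.R876*	nonsense	50.0
c13_PT	APC	p.E1284*	nonsense	50.0
c13_synPUL_1	APC	p.E1284*	nonsense	50.0
c13_synPUL_2	APC	p.E1284*	nonsense	50.0
c13_synPUL_1	ERBB4	p.D300N	missense	50.0
c13_synPUL_2	ERBB4	p.D300N	missense	50.0
c13_PT	KRAS	p.G12D	missense	19.83
c13_synHEP_1	KRAS	p.G12V	missense	16.44
c13_synPUL_1	KRAS	p.G12V	missense	5.62
c13_synPUL_2	KRAS	p.G12V	missense	25.72
c14_PT	APC	p.T1430Pfs*	frameshift	50.0
c14_synHEP_1	APC	p.T1430Pfs*	frameshift	50.0
c14_synHEP_2	APC	p.T1430Pfs*	frameshift	50.0
c14_synPUL_1	APC	p.T1430Pfs*	frameshift	50.0
c14_PT	NRAS	p.Q61R	missense	44.31
c14_synHEP_1	NRAS	p.Q61R	missense	66.91
c14_synHEP_2	NRAS	p.Q61R	missense	44.74
c14_synPUL_1	NRAS	p.Q61R	missense	46.17
c14_PT	TP53	p.R175H	missense	50.0
c14_synHEP_1	TP53	p.R175H	missense	50.0
c14_synHEP_2	TP53	p.R175H	missense	50.0
c14_synPUL_1	TP53	p.R175H	missense	50.0
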
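# RAS hotspot calls per specimen (raw, pre-filter); af_percent 0-100
specimen_id	gene	hgvs_p	consequence	af_percent
c01_PT	KRAS	p.G12D	missense	55.59
c01_synHEP_1	KRAS	p.G12D	missense	97.28
c01_metPUL_1	KRAS	p.G12D	missense	16.77
c02_PT	KRAS	p.G12V	missense	53.59
c02_synHEP_1	KRAS	p.G12V	missense	89.98
c02_synPUL_1	KRAS	p.G12V	missense	47.32
c02_synPUL_2	KRAS	p.G12V	missense	32.82
c03_PT	KRAS	p.G12V	missense	21.92
c03_metHEP_1	KRAS	p.G12V	missense	45.26
c03_metPUL_2	KRAS	p.G12V	missense	21.22
c03_metPUL_3	KRAS	p.G12V	missense	34.0
c05_PT	KRAS	p.G12A	missense	24.18
c05_synHEP_1	KRAS	p.G12A	missense	9.7
c05_synPUL_1	KRAS	p.G12A	missense	17.72
c05_synPUL_2	KRAS	p.G12A	missense	36.04
c06_PT	KRAS	p.G12V	missense	22.85
c06_metPUL_1	KRAS	p.G12V	missense	26.73
c08_PT	KRAS	p.G13D	missense	34.16
c08_synHEP_1	KRAS	p.G13D	missense	50.44
c08_synPUL_1	KRAS	p.G13D	missense	31.43
c08_metPUL_1	KRAS	p.G13D	missense	12.85
c12_PT	KRAS	p.G12A	missense	99.74
c12_synHEP_1	KRAS	p.G12A	missense	56.72
c12_metPUL_1	KRAS	p.G12A	missense	34.15
c12_metPUL_2	KRAS	p.G12A	missense	19.63
c13_PT	KRAS	p.G12D	missense	19.83
c13_synHEP_1	KRAS	p.G12V	missense	16.44
c13_synPUL_1	KRAS	p.G12V	missense	5.62
c13_synPUL_2	KRAS	p.G12V	missense	25.72
c14_PT	NRAS	p.Q61R	missense	44.31
c14_synHEP_1	NRAS	p.Q61R	missense	66.91
c14_synHEP_2	NRAS	p.Q61R	missense	44.74
c14_synPUL_1	NRAS	p.Q61R	missense	46.17
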
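glycolysis22	core glycolytic enzyme signature (22 genes)	SLC2A1	HK1	HK2	HK3	GPI	PFKL	PFKM	PFKP	ALDOA	ALDOB	ALDOC	TPI1	GAPDH	PGK1	PGAM1	PGAM4	ENO1	ENO2	ENO3	PKLR	PKM	LDHA
hypoxia14	hypoxia response signature (14 genes)	ALDOA	MIF	TUBB6	P4HA1	SLC2A1	PGAM1	ENO1	LDHA	CDKN3	TPI1	NDRG1	VEGFA	ACOT7	ADM
glycolysis16	glycolysis signature with hypoxia-overlap genes removed (16 genes)	HK1	HK2	HK3	GPI	PFKL	PFKM	PFKP	ALDOB	ALDOC	GAPDH	PGK1	PGAM4	ENO2	ENO3	PKLR	PKM
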
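Selected TFs	Description	Chromosome locations and promoter ID	Target genes	Number of TGs
ZNF207	Zinc finger protein 207	17q12, promoter ID: 17074	GNB1, CLIP1, SFRS18, CSNK1D, SFPQ, CSNK1A1, ASNS, ZBTB20, TUBB, TM2D1, TIMM17A, ENO1, ASH1L, NONO, KPNA2, REEP5, NSF, HSPD1, UBE2D3, DICER1, and G3BP1	21
BUB3	BUB3 budding uninhibited by benzimidazoles 3 homolog	10q26 promoter ID: 5046	TARDBP, ATP1B1, SFPQ, GNB1, CLIP1, SET, ARPC5L, NCOA1, NOL5A, PPIA, CEP27, REEP5, ENO1, ASNS, ZBTB20, HSPD1, PSMB1, NONO, and KPNA2	19
PTBP1	Polypyrimidine tract binding protein 1	19p13.3 promoter ID: 20018	PABPN1, UBL3, REEP5, KIAA0232, SET, G3BP1, ENO1, GTF2I, SMARCA4, ASH1L, WDR1, CSNK1D, HSP90AB1, TUBB, FKBP1A, YWHAZ, HSPD1, VAMP4, and NONO	19
ZBTB20	Zinc finger and BTB domain containing 20	3q13.2 promoter ID: 119577	POGZ, NFIB, CIRBP, TIMM17A, CEP27, SNRPN, ARHGAP5, TUBB, RUFY3, EZH1, NCOA1, GSTA4, KTN1, RPL35A, GPRASP1, PDE4C, SLC35E1, RABGEF1, and ZNF160	19
COPA	Coatomer protein complex, subunit alpha	1q23-25 promoter ID: 2753	G3BP1, TM2D1, GNB1, GTF2I, RIPK5, DCTN4, SCAMP1, HSPA8, RAB6A, CANX, WDR1, ACTB, CSNK1A1, HSP90AB1, and YWHAZ	15
E2F4	E2F transcription factor 4, p107/p130 binding	16q21-q22 promoter ID: 15321	RUFY3, NTRK2, GABRB2, ENO1, BAIAP2, KTN1, DPP6, PDE4C, EZH1, ITFG1, NECAP1, JAK1, NLRP1, and CHERP	14
POLR2E	Polymerase (RNA) II (DNA directed) polypeptide E, 25 kDa	19p13.3 promoter ID: 22868	SMARCA4, ASH1L, RIPK5, HSBP1, UBE2D3, GNB1, HSPA8, NONO, GSTO1, PGK1, ENO1, WDR1, FKBP1A, and HSP90AB1	14
STIP1	Stress-induced phosphoprotein 1	11q13 promoter ID: 6654	SFPQ, HSBP1, GTF2I, FAM108B1, GNB1, G3BP1, RAB6A, WDR1, HSPA8, ENO1, NONO, YWHAZ, HSPD1, and HSP90AB1	14
ANAPC5	Anaphase promoting complex subunit 5	12q24.31 promoter ID: 9688	CEP27, FAM108B1, G3BP1, GTF2I, HSBP1, HSP90AB1, HSPA8, NONO, PGK1, PSMA1, RAB6A, RIPK5, and YWHAZ	13
RNF38	Ring finger protein 38	9p13-12 promoter ID: 42818	REEP5, SSX2IP, DCTN4, DCUN1D4, HSPA8, C1orf43, SFPQ, ASH1L, ITFG1, HSP90AB1, YWHAZ, MGEA5, and FOXJ3	13
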
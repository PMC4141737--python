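# Site roster for the TCR/CD28 model (reconstructed from the network narrative,
# not the original supplementary site table).  16 measured pTyr sites span the
# 10 measured proteins; receptor-chain sites are modeled but flagged unmeasured.
# site_class: 1 = phosphorylated without prior receptor phosphorylation,
# 2 = phosphorylated after receptor phosphorylation, 3 = dephosphorylated.
protein	residue	observable	site_class	measured
LCK	192	LCK_Y192_P	3	True
LCK	394	LCK_Y394_P	1	True
LCK	505	LCK_Y505_P	3	True
ZAP70	292	ZAP70_Y292_P	2	True
ZAP70	493	ZAP70_Y493_P	2	True
LAT	191	LAT_Y191_P	2	True
LAT	226	LAT_Y226_P	2	True
LCP2	128	LCP2_Y128_P	2	True
LCP2	145	LCP2_Y145_P	2	True
PLCG1	771	PLCG1_Y771_P	2	True
PLCG1	783	PLCG1_Y783_P	2	True
WAS	291	WAS_Y291_P	1	True
PTPN6	566	PTPN6_Y566_P	1	True
PAG1	163	PAG1_Y163_P	3	True
DOK1	449	DOK1_Y449_P	3	True
DOK2	299	DOK2_Y299_P	3	True
CD3G	171	CD3G_Y171_P	1	False
CD3E	188	CD3E_Y188_P	1	False
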
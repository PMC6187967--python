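gene_name	group_id	species	gene_id	log2fc	adj_p	is_ortholog
NFR1		Ct	Ct_CtTrNR03429	-0.37	0.151	1
NFR1		Dg	Dg_DgTrNR03578	2.75	0.000	1
NFR1		Dg	Dg_DgTrNR03579	-1.39	0.000	1
NFR1		Dg	Dg_DgTrNR03580	2.54	0.000	1
NFR1		Mt	Mt_Medtr5g086130	-2.10	0.000	1
NFR5		Ct	Ct_CtTrNR01660			0
NFR5		Ct	Ct_CtTrNR02016			0
NFR5		Ct	Ct_CtTrNR02556			0
NFR5		Ct	Ct_CtTrNR03429			0
NFR5		Ct	Ct_CtTrNR03658			0
NFR5		Ct	Ct_CtTrNR10088			0
NFR5		Ct	Ct_CtTrNR13226			0
NFR5		Ct	Ct_CtTrNR13284			0
NFR5		Ct	Ct_CtTrNR14238			0
NFR5		Ct	Ct_CtTrNR14293			0
NFR5		Dg	Dg_DgTrNR09631	-1.52	0.000	1
NFR5		Mt	Mt_Medtr5g019040	-2.43	0.000	1
SYMRK	MergedOrthoGroup005636	Ct	Ct_CtTrNR07134	-0.19	0.413	1
SYMRK	MergedOrthoGroup005636	Dg	Dg_DgTrNR12393	0.46	0.000	1
SYMRK	MergedOrthoGroup005636	Mt	Mt_Medtr5g030920	0.60	0.002	1
SYMREM	MergedOrthoGroup006520	Ct	Ct_CtTrNR08408	2.10	0.003	1
SYMREM	MergedOrthoGroup006520	Dg	Dg_DgTrNR05672	5.65	0.000	1
SYMREM	MergedOrthoGroup006520	Mt	Mt_Medtr5g010590	-0.22	0.775	1
SYMREM	MergedOrthoGroup006520	Mt	Mt_Medtr8g097320	9.88	0.000	1
HMGR		Ct	Ct_CtTrNR06569			0
HMGR		Ct	Ct_CtTrNR06801			0
HMGR		Ct	Ct_CtTrNR08716			0
HMGR		Ct	Ct_CtTrNR12229			0
HMGR		Dg	Dg_DgTrNR07804			0
HMGR		Dg	Dg_DgTrNR14611			0
HMGR		Dg	Dg_DgTrNR14612			0
HMGR		Mt	Mt_Medtr5g087550	-1.35	0.000	1
NUP85	MergedOrthoGroup003212	Ct	Ct_CtTrNR03893	-0.87	0.020	1
NUP85	MergedOrthoGroup003212	Dg	Dg_DgTrNR02299	0.12	0.132	1
NUP85	MergedOrthoGroup003212	Mt	Mt_Medtr1g006690	-0.19	0.665	1
NUP133	MergedOrthoGroup009404	Ct	Ct_CtTrNR12969	-0.20	0.263	1
NUP133	MergedOrthoGroup009404	Dg	Dg_DgTrNR15290	0.58	0.000	1
NUP133	MergedOrthoGroup009404	Lj	Lj_Lj2g3v3337540			1
NUP133	MergedOrthoGroup009404	Lj	Lj_Lj0g3v0050449			1
NUP133	MergedOrthoGroup009404	Mt	Mt_Medtr5g097260	-0.48	0.064	1
CASTOR	MergedOrthoGroup008762	Ct	Ct_CtTrNR11902	-0.39	0.071	1
CASTOR	MergedOrthoGroup008762	Dg	Dg_DgTrNR14656	0.37	0.001	1
CASTOR	MergedOrthoGroup008762	Mt	Mt_Medtr7g117580	-0.23	0.431	1
POLLUX	MergedOrthoGroup009011	Ct	Ct_CtTrNR12292	-0.43	0.090	1
POLLUX	MergedOrthoGroup009011	Dg	Dg_DgTrNR14917	-0.83	0.000	1
POLLUX	MergedOrthoGroup009011	Mt	Mt_Medtr2g005870	1.61	0.000	1
CCAMK	MergedOrthoGroup006145Sub001	Ct	Ct_CtTrNR07875	-0.49	0.064	1
CCAMK	MergedOrthoGroup006145Sub001	Dg	Dg_DgTrNR14486	0.02	0.857	1
CCAMK	MergedOrthoGroup006145Sub001	Mt	Mt_Medtr8g043970	0.59	0.004	1
CYCLOPS	MergedOrthoGroup005459Sub002	Ct	Ct_CtTrNR09813	0.25	0.294	1
CYCLOPS	MergedOrthoGroup005459Sub002	Dg	Dg_DgTrNR00459	1.60	0.000	1
CYCLOPS	MergedOrthoGroup005459Sub002	Mt	Mt_Medtr5g026850	3.18	0.000	1
NSP1	MergedOrthoGroup009317	Ct	Ct_CtTrNR12805	-0.10	0.595	1
NSP1	MergedOrthoGroup009317	Dg	Dg_DgTrNR11911	0.96	0.000	1
NSP1	MergedOrthoGroup009317	Mt	Mt_Medtr3g085310	0.00	1.000	1
NSP1	MergedOrthoGroup009317	Mt	Mt_Medtr8g020840	1.62	0.000	1
NSP2	MergedOrthoGroup000090	Ct	Ct_CtTrNR00101	0.50	0.232	1
NSP2	MergedOrthoGroup000090	Dg	Dg_DgTrNR00363	-1.38	0.000	1
NSP2	MergedOrthoGroup000090	Dg	Dg_DgTrNR01580	0.99	0.001	1
NSP2	MergedOrthoGroup000090	Mt	Mt_Medtr3g072710	-1.34	0.000	1
NSP2	MergedOrthoGroup000090	Mt	Mt_Medtr5g058860	-2.59	0.000	1
ERN1	MergedOrthoGroup010414	Ct	Ct_CtTrNR15219	-2.56	0.003	1
ERN1	MergedOrthoGroup010414	Dg	Dg_DgTrNR02845	-0.66	0.006	1
ERN1	MergedOrthoGroup010414	Dg	Dg_DgTrNR10008	4.95	0.000	1
ERN1	MergedOrthoGroup010414	Mt	Mt_Medtr6g029180	-2.53	0.000	1
ERN1	MergedOrthoGroup010414	Mt	Mt_Medtr7g085810	-0.39	0.373	1
NIN	MergedOrthoGroup008966	Ct	Ct_CtTrNR12221	5.48	0.003	1
NIN	MergedOrthoGroup008966	Ct	Ct_CtTrNR12222	6.47	0.004	1
NIN	MergedOrthoGroup008966	Dg	Dg_DgTrNR00885	8.30	0.000	1
NIN	MergedOrthoGroup008966	Dg	Dg_DgTrNR00886	7.56	0.000	1
NIN	MergedOrthoGroup008966	Mt	Mt_Medtr5g099060	7.42	0.000	1
LHK1	MergedOrthoGroup007561	Ct	Ct_CtTrNR09972	1.16	0.156	1
LHK1	MergedOrthoGroup007561	Dg	Dg_DgTrNR03717	-0.92	0.000	1
LHK1	MergedOrthoGroup007561	Lj	Lj_Lj0g3v0108729			1
LHK1	MergedOrthoGroup007561	Mt	Mt_Medtr2g067240	0.00	1.000	1
LHK1	MergedOrthoGroup007561	Mt	Mt_Medtr5g044100	0.00	1.000	1
LHK1	MergedOrthoGroup007561	Mt	Mt_Medtr8g106150	-0.22	0.524	1
PIR		Ct	Ct_CtTrNR13403	0.13	0.688	1
PIR		Dg	Dg_DgTrNR01709	0.17	0.048	1
PIR		Dg	Dg_DgTrNR07598	-0.51	0.000	1
PIR		Lj	Lj_Lj1g3v5020900			1
RPG	MergedOrthoGroup006667Sub001	Ct	Ct_CtTrNR08628	-0.78	0.022	1
RPG	MergedOrthoGroup006667Sub001	Ct	Ct_CtTrNR14741	5.14	0.003	1
RPG	MergedOrthoGroup006667Sub001	Dg	Dg_DgTrNR05600	8.90	0.000	1
RPG	MergedOrthoGroup006667Sub001	Dg	Dg_DgTrNR07056	-0.25	0.102	1
RPG	MergedOrthoGroup006667Sub001	Mt	Mt_Medtr1g090807	6.45	0.000	1
CERBERUS	MergedOrthoGroup002490Sub002	Ct	Ct_CtTrNR11435	0.24	0.265	1
CERBERUS	MergedOrthoGroup002490Sub002	Dg	Dg_DgTrNR05473	0.87	0.000	1
CERBERUS	MergedOrthoGroup002490Sub002	Mt	Mt_Medtr1g090320	1.25	0.000	1
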
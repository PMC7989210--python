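# Multi-omics candidate genes distinguishing HCM from control hearts (53 protein-coding genes).
# Columns: gene symbol; cardiomyocyte expression class (Human Protein Atlas tiers);
# plasma/serum detectability (Human Plasma Proteome Project); rank in the O2PLS joint-component
# analysis (1 = largest contribution); transcriptome log2FC (HCM vs control, DESeq2);
# proteome log2FC (HCM vs control); whether a differentially acetylated region within 50 kb of
# the TSS changed in the matching direction (yes/no); log2FC in mutant-vs-control engineered
# cardiomyocytes (NA = not significant / not matching).
symbol	cm_expression	plasma	o2pls_rank	rna_log2fc	protein_log2fc	acetylome_match_50kb	external_cm_log2fc
AASS	Medium	Detected	1046	-1.279808444	-0.773247332	yes	-0.414920406
ABHD11	Medium	Detected	669	1.137180651	0.640971138	no	NA
ACTN2	High	Detected	1597	0.570095367	0.184641682	no	NA
ADH1B	Low	Detected	1281	-1.081956134	-0.880289941	no	NA
ARHGAP1	Medium	Detected	1512	1.763584	0.597291165	yes	NA
ASPN	Not detected	Detected	454	2.204317	1.77725136	yes	NA
ATP2A2	High	Detected	728	-1.466783433	-0.353968239	no	NA
BGN	Medium	Detected	1012	1.832538	1.533815477	no	0.588280947
C6	Not detected	Detected	130	-1.776237721	-0.695516121	no	NA
CA3	Not detected	Detected	43	4.518344	1.686864533	no	NA
CHCHD6	Medium	Not detected	910	2.003514	0.778880421	no	NA
CHDH	Low	Not detected	98	-2.209806815	-1.442995937	yes	NA
CLGN	Not detected	Not detected	1751	-1.088152172	-0.808838009	yes	NA
DDAH1	Not detected	Detected	452	1.764206	1.115473264	yes	NA
EFHD1	Not detected	Not detected	682	1.865517	1.264459654	yes	0.318203232
FGF12	No data	Not detected	62	-2.353022973	-1.079274106	yes	-0.30374396
FHL2	High	Not detected	440	-1.255001122	-0.411782639	no	NA
FMOD	No data	Detected	395	2.594323	1.414783229	yes	NA
FSCN1	Not detected	Detected	1276	1.759951	0.971207984	yes	0.456046007
GATM	Not detected	Detected	277	1.545734889	1.002695568	yes	NA
GPD1	Medium	Detected	1708	-1.687472289	-1.343895776	yes	-0.410181446
GPD1L	No data	Not detected	1342	-1.066784553	-0.526757351	no	NA
HSPA2	Not detected	Detected	171	3.490234	2.652261545	yes	NA
HSPB6	High	Detected	647	2.253803	0.392977171	no	-3.170003763
LDHA	Not detected	Detected	974	-1.219034333	-0.474108409	yes	NA
LTBP2	Not detected	Detected	829	2.1279	2.317830122	yes	NA
LUM	Not detected	Detected	217	2.135187	0.959297891	no	0.512857369
MAP4	Medium	Detected	717	1.851811	1.003525943	yes	-0.223635511
MCAM	Low	Detected	1338	1.653115	1.104716402	yes	-0.264831197
MFAP2	Not detected	Not detected	1303	1.84358	0.70531399	yes	-0.357062335
MYH6	High	Detected	40	-2.919038787	-1.009056575	no	NA
MYL12A	Medium	Detected	64	2.419604	0.578322489	no	-0.14329672
MYLK3	High	Not detected	1904	-1.007764366	-0.747812735	no	0.127033902
NES	Medium	Detected	641	1.806419	1.936943877	no	NA
NPPA	Medium	Detected	13	1.549472808	0.747781872	yes	0.542363796
NUDT4	High	Not detected	1531	-1.093022558	-0.695436878	no	0.207067638
PDK4	High	Not detected	1724	-1.07459529	-0.607585372	yes	NA
RAB24	No data	Not detected	1085	2.211788	1.041018278	no	NA
RRAS	High	Detected	1642	1.788982	0.447281909	no	NA
S100A6	Not detected	Detected	1486	1.859224	0.794548978	no	NA
SAA1	No data	Detected	63	-1.173021107	-2.740052623	no	NA
SERPINE2	No data	Detected	338	1.002427623	0.652055032	no	0.714236168
SGCG	High	Not detected	1805	0.707480434	0.430185184	yes	NA
SLC25A5	High	Detected	1634	1.811682	0.613247381	no	NA
SNCA	Not detected	Detected	274	2.629958	1.02410125	no	NA
SORBS2	No data	Detected	1991	1.475585	0.484980733	yes	-0.241151423
STMN1	Not detected	Detected	1211	0.77170211	0.807423435	no	NA
SYNPO2L	High	Not detected	483	2.306538	1.028059491	yes	NA
TANGO2	Low	Detected	1086	1.981163	0.733156318	no	NA
THBS4	Low	Detected	618	2.323482	2.106545221	no	NA
TPM3	Medium	Detected	981	2.116673	1.224815654	no	0.36243013
TPPP	Not detected	Not detected	1374	-0.898226805	-0.830942802	yes	NA
UCHL1	Not detected	Detected	44	5.052289	0.933127805	no	NA
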
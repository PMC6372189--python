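human_gene	candidate	annotation_id	external_id	identity	similarity	evalue	coverage	stats_source	detection_route	domain_match	fold_match	fold_rmsd	fold_n_pairs	residues	published_group	notes
PTGES	MGST-like	CG1742	FBgn0025814	36	54	2e-24	97	sequence-match	pairwise	true	true	1.15	152	R38>R40:identical;R70>R71:identical;E77>E78:identical;R110>R111:identical;Y117>Y118:identical;R126>R128:identical;Y130>F132:equivalent	1	aromatic-ring analog F for Y at the glutathione site
PTGES2	Su(P)	CG4086	FBgn0004465	42	62	3e-70	73	sequence-match	pairwise	true	true	0.814	377	C110>C133:identical	1
AKR1B1	CG6084	CG6084	FBgn0086254	49	68	5e-94	97	sequence-match	pairwise	true	true	0.847	316	Y48>Y50:identical;K77>K79:identical;H110>H112:identical	1	catalytic triad fully conserved
LTA4H	CG10602	CG10602	FBgn0032721	44	62	4e-179	99	sequence-match	pairwise	true	true	0.891	611	H296>H293:identical;H300>H297:identical;E319>E316:identical;E297>E294:identical;D376>D374:identical;Y384>Y382:identical	1	zinc triad plus catalytic E/D/Y conserved
GGT1	GGT	CG6461	FBgn0030932	45	58	4e-133	92	sequence-match	pairwise	true	true	1.126	569	T381>T382:identical;R107>R107:identical;T399>T400:identical;E420>E421:identical	1	autocatalytic threonine and glutamate-binding residues conserved
DPEP1	DPEP	CG6154	FBgn0039420	49	65	3e-125	88	sequence-match	pairwise	true	true	0.523	411	H36>H71:identical;D38>D73:identical;E141>E184:identical;H214>H257:identical;H235>H278:identical	1	zinc-coordinating set conserved
GPX1	PHGPx	CG12013	FBgn0035438	35	52	6e-32	90	sequence-match	pairwise	true	true	0.699	169	U49>C?:equivalent;Q83>Q?:identical;W160>W?:identical	1	selenocysteine read as cysteine at the catalytic position
CPA1	CPA	CG18585	FBgn0031929	35	55	9e-82	98	sequence-match	pairwise	true	true	0.753	419	H179>H178:identical;E182>E181:identical;H306>H305:identical;E380>E382:identical	1	zinc-coordinating set conserved
HPGDS	GST-S1	CG8938	FBgn0010226	36	60	3e-37	98	sequence-match	pairwise	true	true	1.045	160	D93>D139:identical;D96>-:missing;D97>D143:identical	2	amide-for-acid N142 at the D96 site judged case-by-case, not auto-equivalent
PTGES3	CG16817	CG16817	FBgn0037728	27	45	6e-12	83	sequence-match	pairwise	true	true	0.823	160		2	no specific catalytic residue attested; fold and architecture only
CBR1	CBR	CG11200	FBgn0034500	30	45	8e-19	95	sequence-match	pairwise	true	true	1.153	277	N90>N154:identical;Y194>Y233:identical;S139>-:missing	2	catalytic serine of the reductase machinery unattested
HPGD	CG18814	CG18814	FBgn0042137	34	53	9e-35	76	sequence-match	pairwise	true	true	0.715	266	N91>N89:identical;S138>S137:identical;Q148>Q142:proximal;Y151>Y150:identical	2	Q analog rescued only by ~5 A structural proximity
TBXAS1	CYP450-9c1	CG3616	FBgn0015040	31	49	6e-69	97	sequence-match	pairwise	true	true	0.699	518		2	selected on secondary-structure profile; no residue correspondence attested
PTGS1	CG4009	CG4009	FBgn0038469	25	41	1e-10	49	sequence-match	pairwise	false	true	2.660	599	H206>H163:identical;Y384>Y399:identical;H387>H401:identical	3	peroxidase/cyclooxygenase triad present; EGF-like domain absent
PTGS1	Pxt	CG7660	FBgn0261987	22	39	2e-09	59	sequence-match	pairwise	false	true	2.810		H206>H222:identical;Y384>Y564:identical;H387>H568:identical	3
PTGS1	Cardinal	CG6969	FBgn0263986	20	36	1e-05	61	sequence-match	pairwise	false	true	2.942		H206>H?:identical;Y384>Y?:identical;H387>H?:identical	3	triad attested without stated candidate positions
PTGDS	Nlaz	CG33126	FBgn0053126	20	62	9e-13	97	profile-match	profile-iterative	true	true	2.084	190	C65>C67:identical	3	lipocalin beta-barrel; catalytic cysteine analog
PTGIS	CYP450-4D2	CG3466	FBgn0011576	26	72	3e-70	93	profile-match	profile-iterative	true	true	1.213	500	C441>C449:identical	3	plain pairwise match only 23%/44% at 34% coverage
LTC4S	CG33178	CG33178	FBgn0053178	28	61	4e-4	84	profile-match	profile-iterative	true	true	1.257	150	R30>R51:identical;R31>R53:identical;R104>R139:identical	3	four-helix MAPEG bundle; arginine set conserved
ALOX5AP	CG33177	CG33177	FBgn0053177	33	82	6e-20	88	profile-match	profile-iterative	true	true	1.024	161		3	assigned by family-level similarity; no residue correspondence attested
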
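snp_id	chrom	pos	minor_allele	fst	maf_north	maf_south	gene	category
rs4149264	9	107677211	C	0.2256	0.4856	0.1682	ABCA1	intronic
rs10102377	8	83762822	T	0.2251	0.4097	0.2336		
rs4148475	13	95853574	A	0.2242	0.4676	0.184	ABCC4	intronic
rs1056836	2	38298203	G	0.2037	0.4757	0.1934	CYP1B1	coding
rs1126965	17	70642790	G	0.1931	0.5	0.1822	SLC39A11	3utr
rs17769090	15	70630120	A	0.1636	0.4648	0.2381		
rs6974363	7	47633187	G	0.1421	0.493	0.2333		
rs837395	1	47269338	A	0.1400	0.4897	0.2383	CYP4B1	intronic
rs4646430	2	38306415	G	0.1384	0.4621	0.1981		
rs215101	16	16052973	G	0.1206	0.4752	0.271	ABCC1	intronic
rs12920607	16	73728620	C	0.1183	0.475	0.2736		
rs837398	1	47266422	A	0.1124	0.4897	0.2664	CYP4B1	intronic
rs809367	10	89741806	A	0.1088	0.4307	0.2009		
rs316133	6	52847551	C	0.0957	0.4823	0.2594	GSTA4	intronic
rs6130511	20	42681088	A	0.0916	0.2801	0.1	TOX2	intronic
rs2132845	4	140587125	T	0.0910	0.4255	0.215	MGST2	5utr
rs5761313	22	26313745	T	0.0887	0.4964	0.2804	MYO18B	intronic
rs10485805	20	54945783	G	0.0853	0.4397	0.2336	AURKA	intronic
rs10489142	1	7363310	G	0.0835	0.4507	0.3364	CAMTA1	intronic
rs2274928	13	24044546	A	0.0779	0.3601	0.4346	LINC00327	intronic
rs11935505	4	145226422	A	0.0758	0.04643	0.1682		
rs1566869	12	52266348	A	0.0695	0.3406	0.1682		
rs1884897	20	6612832	G	0.0695	0.2812	0.1215		
rs4530975	7	104415415	T	0.0679	0.1862	0.05607	LHFPL3	intronic
rs6024831	20	54938464	G	0.0675	0.4161	0.3915	FAM210B	intronic
rs1160798	6	112438446	C	0.0661	0.06897	0.1934	LAMA4	intronic
rs2158196	4	114416596	C	0.0658	0.2391	0.09434	CAMK2D	intronic
rs16961766	13	103899499	A	0.0645	0.3143	0.1524		
rs10962015	9	15387949	A	0.0638	0.2482	0.1028		
rs6884962	5	172682382	A	0.0623	0.4896	0.3271		
rs17126776	1	239311625	A	0.0603	0.1759	0.3318		
rs2755209	13	41137804	C	0.0602	0.25	0.1075	FOXO1	intronic
rs9783586	13	108361559	T	0.0601	0.2671	0.4393	FAM155A	intronic
rs10968093	9	27753227	A	0.0594	0.06338	0.1776		
rs2458286	8	103978699	T	0.0591	0.4424	0.3774		
rs4875364	8	4444592	C	0.0583	0.3094	0.1557	CSMD1	intronic
rs11145506	9	80264584	T	0.0578	0.3821	0.217	GNA14	intronic
rs11604366	1	128887766	C	0.0577	0.2695	0.4387		
rs9881633	3	112881539	T	0.0574	0.3	0.472	RP11_572M11.3	intronic
rs5762448	22	28408444	C	0.0573	0.3514	0.1916	TTC28	intronic
rs6467991	7	83954737	C	0.0570	0.344	0.4811		
rs10089677	8	122660248	A	0.0569	0.2329	0.09813		
rs1923254	13	41084241	G	0.0567	0.3776	0.2143		
rs781380	6	85142665	C	0.0567	0.2817	0.1355		
rs762541	13	112811428	A	0.0564	0.3403	0.486		
rs2922249	6	127954614	C	0.0564	0.09441	0.2196		
rs2294088	8	124526607	A	0.0564	0.4514	0.2804	FBXO32	intronic
rs12289262	11	12894758	T	0.0560	0.3986	0.2336	TEAD1	intronic
rs4937523	11	130347190	T	0.0558	0.2937	0.4626	ADAMTS15	intronic
rs10807768	7	13662014	A	0.0554	0.3169	0.1651		
rs976272	14	61449328	A	0.0551	0.4897	0.3178	SLC38A6	coding
rs13027801	2	143602503	C	0.0551	0.2862	0.4533		
rs17701834	19	22121458	G	0.0549	0.2172	0.08879		
rs7193843	16	54677292	G	0.0548	0.1448	0.285		
rs7097885	10	16506501	C	0.0542	0.2832	0.4486	PTER	intronic
rs2791398	1	245965551	G	0.0540	0.05944	0.1651	SMYD3	intronic
rs10486802	7	39723768	A	0.0531	0.1884	0.07009	RALA	intronic
rs8031676	15	96910440	C	0.0529	0.4306	0.2664		
rs7186479	16	82602736	C	0.0527	0.2517	0.1168		
rs6054383	20	6584604	T	0.0526	0.3986	0.2383		
rs4460308	7	104420060	C	0.0521	0.1866	0.07009	LHFPL3	intronic
rs3775779	4	70709207	A	0.0520	0.476	0.3551	SULT1E1	intronic
rs9375877	6	132690239	G	0.0517	0.4862	0.3458	MOXD1	intronic
rs2180691	20	54964361	A	0.0517	0.45	0.2857	AURKA	intronic
rs7778955	7	39740487	G	0.0517	0.1438	0.04206	RALA	intronic
rs4608114	12	92384658	A	0.0517	0.4366	0.2736	C12orf79	intronic
rs6946733	7	106670288	A	0.0514	0.4281	0.2664		
rs816650	10	601089	T	0.0514	0.114	0.2406	DIP2C	intronic
rs6490805	13	24084809	C	0.0507	0.08394	0.1981		
rs17171480	7	35585669	A	0.0506	0.09286	0.2103		
rs17015112	3	77319487	G	0.0505	0.4545	0.3785	ROBO2	intronic
rs573186	3	124178276	C	0.0503	0.2483	0.1168	KALRN	intronic
rs10752609	1	154791128	A	0.0501	0.3147	0.1698	KCNN3	intronic
rs1862737	16	75281964	C	0.0500	0.4155	0.257	BCAR1	5utr
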
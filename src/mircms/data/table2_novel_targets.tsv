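mirna_id	transcript_id	category	cleavage_site	mf_norm_reads	cms_norm_reads	annotation
PC-3p-30	AT4G28000.1	4	77	1	.	P-loop containing nucleoside triphosphate hydrolases superfamily protein
PC-3p-30	AT4G38850.1	4	272	.	0.111111	SAUR-like auxin-responsive protein family
PC-3p-41	AT1G07920.1	3	1202	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT1G07930.1	3	1214	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT1G07930.2	3	983	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT1G07940.1	3	1206	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT1G07940.2	3	1333	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT1G35550.1	4	303	.	0.111111	elongation factor Tu C-terminal domain-containing protein
PC-3p-41	AT5G60390.1	3	1158	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT5G60390.2	3	1158	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-41	AT5G60390.3	3	1148	1	3.361111	GTP binding Elongation factor Tu family protein
PC-3p-65	AT1G18400.1	2	460	2	.	BR enhanced expression 1
PC-3p-65	AT1G18710.1	4	792	0.333333	.	myb domain protein 47
PC-3p-65	AT1G62750.1	3	82	.	0.4	Translation elongation factor EFG/EF2 protein
PC-3p-65	AT1G76720.1	4	1493	0.2	.	eukaryotic translation initiation factor 2 (eIF-2) family protein
PC-3p-65	AT1G76810.1	4	1225	0.2	.	eukaryotic translation initiation factor 2 (eIF-2) family protein
PC-3p-65	AT1G76820.1	4	878	0.2	.	eukaryotic translation initiation factor 2 (eIF-2) family protein
PC-3p-65	AT2G26630.1	4	761	0.25	0.2	transposable element gene
PC-3p-65	AT2G27710.1	3	505	0.535714	0.142857	60S acidic ribosomal protein family
PC-3p-65	AT2G27710.2	3	502	0.535714	0.142857	60S acidic ribosomal protein family
PC-3p-65	AT2G27710.3	3	433	0.535714	0.142857	60S acidic ribosomal protein family
PC-3p-65	AT2G27710.4	3	454	0.535714	0.142857	60S acidic ribosomal protein family
PC-3p-65	AT2G30860.1	3	128	.	1	glutathione S-transferase PHI 9
PC-3p-65	AT2G30860.2	3	128	.	1	glutathione S-transferase PHI 9
PC-3p-65	AT2G33810.1	4	409	1	.	squamosa promoter binding protein-like 3
PC-3p-65	AT3G06870.1	2	585	0.4	.	proline-rich family protein
PC-3p-65	AT4G09255.1	4	62	0.5	.	transposable element gene
PC-3p-65	AT4G11420.1	4	538	.	1	eukaryotic translation initiation factor 3A
PC-3p-65	AT5G21274.1	4	63	.	1	calmodulin 6
PC-3p-65	AT5G57290.2	2	348	3	0.333333	60S acidic ribosomal protein family
PC-3p-65	AT5G57655.1	4	1553	.	0.5	xylose isomerase family protein
PC-3p-65	AT5G57655.2	4	1592	.	0.5	xylose isomerase family protein
PC-5p-12	AT3G25100.1	3	823	0.5	.	cell division cycle 45
PC-5p-12	AT5G28800.1	4	13	0.166667	.	unknown protein
PC-5p-12	AT5G40340.1	2	380	0.85	.	Tudor/PWWP/MBT superfamily protein 6
PC-5p-12	AT5G52830.1	4	1040	.	1	WRKY DNA-binding protein 27
PC-5p-12	AT5G62750.1	2	212	2	.	unknown protein
PC-5p-20	AT2G28056.1	2	677	2	.	MIR172/MIR172A; miRNA
PC-5p-32	AT1G70700.1	4	958	.	0.5	TIFY domain/Divergent CCT motif family protein
PC-5p-32	AT1G70700.2	4	886	.	0.5	TIFY domain/Divergent CCT motif family protein
PC-5p-32	AT2G24270.1	2	1736	0.75	.	aldehyde dehydrogenase 11A3
PC-5p-32	AT2G24270.2	2	1633	0.75	.	aldehyde dehydrogenase 11A3
PC-5p-32	AT2G24270.3	2	1622	0.75	.	aldehyde dehydrogenase 11A3
PC-5p-32	AT2G24270.4	2	1633	0.75	.	aldehyde dehydrogenase 11A3
PC-5p-32	AT2G39720.1	4	1004	.	1	RING-H2 finger C2A
PC-5p-51	AT2G20585.1	4	375	0.333333	.	nuclear fusion defective 6
PC-5p-51	AT2G20585.2	4	375	0.333333	.	nuclear fusion defective 6
PC-5p-51	AT2G20585.3	4	375	0.333333	.	nuclear fusion defective 6
PC-5p-52	AT2G27760.1	4	42	.	0.5	tRNAisopentenyltransferase 2
PC-5p-52	AT2G45960.1	4	148	0.166667	.	plasma membrane intrinsic protein 1B
PC-5p-52	AT2G45960.2	4	148	0.166667	.	plasma membrane intrinsic protein 1B
PC-5p-52	AT2G45960.3	4	148	0.166667	.	plasma membrane intrinsic protein 1B
PC-5p-52	AT2G47700.1	4	32	.	0.5	RING/U-box superfamily protein
PC-5p-52	AT3G03340.1	4	67	0.1	0.1	LUC7 related protein
PC-5p-52	AT3G09980.1	4	71	0.333333	.	Family of unknown function (DUF662)
PC-5p-52	AT3G57870.1	4	81	1	.	sumo conjugation enzyme 1
PC-5p-52	AT5G18310.1	0	31	1.5	.	unknown protein
PC-5p-52	AT5G18310.2	0	24	1.5	.	unknown protein
PC-5p-53	AT3G46040.1	3	131	1	.	ribosomal protein S15A D
PC-5p-53	AT4G02660.1	2	8902	1	.	Beige/BEACH domain ;WD domain, G-beta repeat protein
PC-5p-53	AT4G34230.1	2	178	.	1	cinnamyl alcohol dehydrogenase 5
PC-5p-53	AT4G34230.2	2	175	.	1	cinnamyl alcohol dehydrogenase 5
PC-5p-53	AT5G53530.1	4	993	1	.	vacuolar protein sorting 26A
PC-5p-53	AT5G59850.1	2	122	2.333333	0.333333	Ribosomal protein S8 family protein
PC-5p-56	AT4G12800.1	2	385	4	4	photosystem I subunit l
PC-5p-56	AT5G19290.1	4	387	.	1	alpha/beta-Hydrolases superfamily protein
PC-5p-64	AT1G20260.1	4	648	.	0.5	ATPase, V1 complex, subunit B protein
PC-5p-64	AT1G50500.1	4	533	0.333333	.	Membrane trafficking VPS53 family protein
PC-5p-64	AT1G50500.2	4	548	0.333333	.	Membrane trafficking VPS53 family protein
PC-5p-64	AT1G67410.1	0	1638	6	.	Exostosin family protein
PC-5p-64	AT1G71680.1	4	1781	1	.	Transmembrane amino acid transporter family protein
PC-5p-64	AT1G76030.1	4	654	.	0.5	ATPase, V1 complex, subunit B protein
PC-5p-64	AT2G38040.1	4	1257	0.5	2.5	carboxyltransferase alpha subunit
PC-5p-64	AT2G38040.2	4	1232	0.5	2.5	carboxyltransferase alpha subunit
PC-5p-64	AT4G25050.1	4	355	.	0.5	acyl carrier protein 4
PC-5p-64	AT4G25050.2	4	416	.	0.5	acyl carrier protein 4
PC-5p-64	AT4G35300.1	4	2370	.	0.2	tonoplast monosaccharide transporter2
PC-5p-64	AT4G35300.2	4	2371	.	0.2	tonoplast monosaccharide transporter2
PC-5p-64	AT4G35300.3	4	2331	.	0.2	tonoplast monosaccharide transporter2
PC-5p-64	AT4G35300.4	4	2370	.	0.2	tonoplast monosaccharide transporter2
PC-5p-64	AT4G35300.5	4	2251	.	0.2	tonoplast monosaccharide transporter2
PC-5p-64	AT4G36640.1	1	281	1.5	.	Sec14p-like phosphatidylinositol transfer family protein
PC-5p-64	AT4G36640.2	1	185	1.5	.	Sec14p-like phosphatidylinositol transfer family protein
PC-5p-64	AT5G19770.1	4	558	0.5	.	tubulin alpha-3
PC-5p-64	AT5G19780.1	4	591	0.5	.	tubulin alpha-5
PC-5p-64	AT5G54960.1	4	1869	0.5	0.5	pyruvate decarboxylase-2
PC-5p-74	AT3G09800.1	2	689	3	2	SNARE-like superfamily protein
PC-5p-74	AT3G17900.1	4	905	.	1	unknown protein
PC-5p-74	AT3G53710.1	4	1391	0.5	.	ARF-GAP domain 6
PC-5p-74	AT3G53710.2	4	1333	0.5	.	ARF-GAP domain 6
PC-5p-74	AT3G56850.1	4	1331	.	1	ABA-responsive element binding protein 3
PC-5p-74	AT4G09510.1	0	1861	6.5	3	cytosolic invertase 2
PC-5p-74	AT4G09510.2	0	1916	6.5	3	cytosolic invertase 2
PC-5p-74	AT5G27860.1	4	463	0.5	.	unknown protein
PC-5p-74	AT5G27860.2	4	463	0.5	.	unknown protein
PC-5p-74	AT5G39740.1	2	838	0.75	0.5	ribosomal protein L5 B
PC-5p-74	AT5G39740.2	2	880	0.75	0.5	ribosomal protein L5 B
PC-5p-74	AT5G47040.1	1	2243	.	4	lon protease 2
PC-5p-74	ATMG01360.1	2	1453	13	2	cytochrome oxidase
PC-5p-74	AT4G31480.1	4	2477	0.333333	.	Coatomer, beta subunit
PC-5p-74	AT4G31480.2	4	2557	0.333333	.	Coatomer, beta subunit
PC-5p-74	AT4G31490.1	4	2399	0.333333	.	Coatomer, beta subunit
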
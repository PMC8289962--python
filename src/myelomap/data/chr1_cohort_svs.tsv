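sample_id	group	sv_type	size_kbp	cytobands	chrom_a	pos_a	chrom_b	pos_b	vaf_pct	n_genes
EMM1	EMM	Intra-chrom	14502	1p36.33-p36.13	1	1451742	1	16010418	8	230
EMM1	EMM	Deletion	12.3	1p32.3	1	54437326	1	54468426	13	0
EMM1	EMM	Deletion	0.7	1p31.1	1	73986848	1	73989906	49	0
EMM1	EMM	Deletion	0.7	1q21.2	1	149255041	1	149297922	12	0
EMM1	EMM	Deletion	83.9	1q31.1	1	188862967	1	188948998	13	0
EMM1	EMM	Deletion	0.9	1q41	1	219227885	1	219230864	69	0
EMM2	EMM	Intra-chrom	46876	1p35.1-p31.1	1	33649122	1	80528558	13	475
EMM2	EMM	Deletion	1611	1p32.3	1	52146402	1	53764220	6	22
EMM2	EMM	Deletion	20.0	1p32.2	1	56859220	1	56897293	5	1
EMM2	EMM	Deletion	311	1p32.2	1	57042204	1	57356850	6	1
EMM2	EMM	Insertion	0.6	1p32.2	1	57981404	1	57987615	27	1
EMM2	EMM	Intra-chrom	57947	1p32.1-p12	1	60494258	1	118466419	9	443
EMM2	EMM	Deletion	14.5	1p31.1	1	70404062	1	70438713	20	1
EMM2	EMM	Deletion	5.5	1p31.1	1	70766057	1	70784216	25	0
EMM2	EMM	Intra-chrom	21501	1p22.2-p13.3	1	89446367	1	110953619	6	175
EMM2	EMM	Deletion	7.3	1q25.3	1	182529994	1	182549190	61	1
EMM3	EMM	Intra-chrom	7575	1p35.2-p34.3	1	30221701	1	37801246	15	120
EMM3	EMM	Intra-chrom	7465	1p35.2-p34.3	1	30860870	1	38353947	8	126
EMM3	EMM	Intra-chrom	12639	1p22.1-p21.1	1	93051297	1	105699124	9	81
EMM3	EMM	Deletion	1.3	1p22.1	1	93329493	1	93335818	10	1
EMM3	EMM	Intra-chrom	12839	1p21.1-p13.2	1	102272272	1	115119846	21	140
EMM3	EMM	Deletion	5.8	1q42.3	1	235342739	1	235355292	18	1
EMM4	EMM	Deletion	53.1	1p36.33	1	1679533	1	1743791	7	3
EMM4	EMM	Insertion	2.5	1p36.12	1	21983384	1	22006562	13	2
EMM4	EMM	Intra-chrom	36076	1p34.2-p31.1	1	39891936	1	75973164	7	363
EMM4	EMM	Deletion	3687	1p34.2-p34.1	1	42633541	1	46350766	8	102
EMM4	EMM	Intra-chrom	119844	1p34.1-1q23.3	1	44054030	1	163946030	8	1175
EMM4	EMM	Insertion	2.5	1p13.2	1	111794239	1	111807945	11	1
EMM4	EMM	Insertion	6.1	1p13.1	1	115530277	1	115543191	14	0
EMM4	EMM	Deletion	0.8	1q31.3	1	195460336	1	195473816	16	0
EMM4	EMM	Insertion	18.6	1q32.2	1	207515921	1	207534396	12	2
EMM4	EMM	Insertion	6.0	1q32.3	1	213171761	1	213205644	12	1
MM1	MM	Insertion	5.9	1p36.33	1	1590522	1	1654114	17	7
MM1	MM	Insertion	59.9	1q21.2	1	149365317	1	149390055	55	10
MM1	MM	Insertion	10.9	1q21.3	1	152289954	1	152296885	13	0
MM1	MM	Deletion	231.9	1q25.1	1	175947709	1	176185749	28	2
MM1	MM	Deletion	3176	1q32.3-q41	1	214386812	1	217572960	21	8
MM1	MM	Insertion	19.9	1q42.12	1	226337005	1	226338164	32	0
MM1	MM	Deletion	315.8	1q43	1	238186340	1	238513554	23	1
MM1	MM	Deletion	31.4	1q43	1	239651938	1	239694630	23	1
MM2	MM	Insertion	5.4	1p36.12	1	20372589	1	20396493	12	1
MM2	MM	Deletion	14.6	1p31.1	1	83171695	1	83186312	19	0
MM2	MM	Duplication	95.5	1q21.2	1	148669395	1	148764931	46	1
MM2	MM	Insertion	2.4	1q23.2	1	161184787	1	161193876	13	1
MM2	MM	Deletion	4.4	1q25.2	1	179360227	1	179368480	28	1
MM3	MM	Translocation	.	1p34.3-19p13.11	1	38291095	19	16838518	15	.
MM3	MM	Translocation	.	1p34.3-19p13.12	1	39900616	19	15299192	18	.
MM3	MM	Deletion	0.6	1q32.1	1	200212204	1	200225458	24	0
MM4	MM	Insertion	14.6	1p36.31	1	5999446	1	6006996	20	0
MM4	MM	Insertion	1.8	1p12	1	119153160	1	119157652	27	0
MM4	MM	Duplication	95.5	1q21.2	1	148669395	1	148764931	49	1
MM4	MM	Insertion	2.4	1q23.3	1	161184787	1	161193876	28	1
MM5	MM	Insertion	23.0	1p36.13	1	16040685	1	16054506	9	0
MM5	MM	Deletion	1.8	1p34.2	1	39074813	1	39085202	18	1
MM5	MM	Deletion	5.4	1p31.3	1	62279900	1	62311886	20	1
MM5	MM	Deletion	0.6	1p31.1	1	72996895	1	73015474	24	0
MM5	MM	Duplication	79.6	1q24.2	1	168300624	1	168380191	60	2
MM5	MM	Insertion	199.5	1q24.2	1	168300624	1	168380191	34	2
MM5	MM	Translocation	.	1q24.3-20q13.2	1	170346977	20	53385582	12	.
MM5	MM	Duplication	57.9	1q42.13	1	227147621	1	227205509	19	1
MM6	MM	Insertion	3.2	1p34.3	1	37899628	1	37903954	15	1
MM6	MM	Deletion	14.6	1p31.1	1	83171695	1	83190595	17	0
MM7	MM	Insertion	5.7	1p36.33	1	1590522	1	1654114	5	0
MM7	MM	Insertion	3.8	1p36.32	1	4070359	1	4096038	5	0
MM7	MM	Deletion	23.2	1p36.12	1	21983384	1	22006562	17	2
MM7	MM	Insertion	3.4	1p34.1	1	44413885	1	44419138	7	1
MM7	MM	Duplication	47.2	1p21.3	1	99166139	1	99213371	7	0
MM7	MM	Insertion	55.4	1p21.3	1	99180335	1	99199495	6	0
MM7	MM	Deletion	721.6	1q21.1	1	143310164	1	144170341	25	9
MM7	MM	Duplication	633.7	1q22-q23.1	1	156251622	1	156885360	52	8
MM7	MM	Deletion	3.0	1q24.1	1	166768561	1	166777221	16	0
MM7	MM	Deletion	0.7	1q32.1	1	200212204	1	200225458	15	0
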
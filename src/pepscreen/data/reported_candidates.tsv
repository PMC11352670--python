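sequence	class	residues	accession	protein_name	score	call
MWKLPMFGCT	ACP	10	P05349	Ribulose bisphosphate carboxylase small subunit, chloroplastic 4	1.0	1
WKLPM	ACP	5	P05349	Ribulose bisphosphate carboxylase small subunit, chloroplastic 4	1.0	1
DLLNIFE	ADP	7	Q84K11	Serine/threonine-protein phosphatase-5	1.0	1
LMAALNLVG	ADP	9	P37222	NADP-dependent malic enzyme, chloroplastic	1.0	1
HWLNTHAVIE	ADP	10	P38416	Linoleate 9S-lipoxygenase B	1.0	1
TFAFQAE	ADP	7	P36181	Heat shock cognate protein 80	1.0	1
QFVTFMK	ADP	7	Q6DUX3	Translationally controlled tumor protein homolog	1.0	1
QEFAHDFQAY	ADP	10	P05117	Polygalacturonase-2	1.0	1
LPHPDGDQFG	ADP	10	P38416	Linoleate 9S-lipoxygenase B	1.0	1
GWAPQVLLLS	ADP	10	K4D422	UDP-Glycosyltransferase 73C4	1.0	1
LAQNNVMFE	ADP	9	NP_001294934	Fructose-bisphosphate aldolase	1.0	1
EMIWDLLVS	ADP	9	Q40140	Aspartic protease	1.0	1
MEMGESP	AHP	7	Q40158	Metallothionein-like protein type 2 B	1.0	1
VEMQDVKYP	AHP	9	NP_001234021	Polygalacturonase-2 precursor	1.0	1
MEEVDVAPPQK	AHP	11	P28032	Alcohol dehydrogenase 2	1.0	1
ANQPLPDDDDEA	AHP	12	P38546	GTP-binding nuclear protein Ran1	1.0	1
VIPKENN	AHP	7	P30264	Catalase isozyme 1	1.0	1
IDWKETPEPH	AHP	10	P30221	Class I heat shock protein	1.0	1
FEKGTHIPP	AHP	9	P37222	NADP-dependent malic enzyme	1.0	1
FYQYNPDS	AHP	8	P29000	Acid beta-fructofuranosidase	1.0	1
VKVPEPT	AHP	7	P31542	ATP-dependent Clp protease ATP-binding subunit ClpA homolog CD4B	1.0	1
PTKGSSVAIFGLGAVGLAAAEGAR	AIP	24	P28032	Alcohol dehydrogenase 2	1.0	1
DSSMAGYMSSKKTMEINPENSIM	AIP	23	P36181	Heat shock cognate protein 80	1.0	1
NQKNLHKRYAYQIVLQTREMLR	AIP	22	Q84K13	Serine/threonine-protein phosphatase 5	1.0	1
DKRIFFTNKSYLPSQTPSGVIR	AIP	22	AAB65766	Lipoxygenase	1.0	1
DTQPPRLPTKAVRVTAEEVR	AIP	20	P54767	Glutamate decarboxylase	1.0	1
DETPELMPLSHVLATKLGAR	AIP	20	P43280	S-adenosylmethionine synthase 1	1.0	1
SAILATPSGERTMTSEQMVY	AIP	20	P08196	Phytoene synthase 1, chloroplastic	1.0	1
CGYSMNSIEGAAVSTIHITPE	AIP	21	ABQ42184	S-adenosylmethionine decarboxylase proenzyme	1.0	1
DGPNASYITPAAL	AMP	13	P08196	Phytoene synthase 1, chloroplastic	1.0	1
DFGWGNPIFGGILKAISFTSFGVSVKN	AMP	27	Q6QLX4	Alcohol acyl transferase	1.0	1
DAGASKTYPQQAGTIRKGGHIVIKNRP	AMP	27	Q9AXQ6	Eukaryotic translation initiation factor 5A-1	1.0	1
DKVCVLSCGISTGLGASLNVAKP	AMP	23	P28032	Alcohol dehydrogenase 2	1.0	1
DFLIGNTSTGYCAGGCAAIV	AMP	20	Q40140	Aspartic protease	1.0	1
DHVGFSCSTSGGAASRGILGPFGVIVIA	AMP	28	P29000	Acid beta-fructofuranosidase	1.0	1
DAGASKTYPQQAGTIRKNGYIVIKGRP	AMP	27	Q9AXQ3	Eukaryotic translation initiation factor 5A-4	1.0	1
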
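circ_id	circbase_id	log2fc	p_value	source_gene
Dme_circ_0009372	Dme_circ_0005033	4.5034	0.007635	Asator
Dme_circ_0006708	Dme_circ_0005241	4.2791	0.012415	Dad
Dme_circ_0004259	Dme_circ_0002098	4.2083	0.014401	shot
Dme_circ_0002070	Dme_circ_0002195	3.9032	0.026301	Scp1
Dme_circ_0010408	Dme_circ_0003710	3.8118	0.031385	CoRest
Dme_circ_0003904	Dme_circ_0003738	3.5948	0.045349	CG33144
Dme_circ_0008175	Dme_circ_0001709	3.5948	0.045412	Nlg1
Dme_circ_0005030	Dme_circ_0002884	3.5765	0.046714	Ccn
Dme_circ_0006667	Dme_circ_0001321	3.5765	0.046714	gish
Dme_circ_0010536	Dme_circ_0000629	3.559	0.048096	slgA
Dme_circ_0008383	Dme_circ_0004519	2.6054	0.043863	mura
Dme_circ_0010134	Dme_circ_0002087	1.1067	0.039466	Stim
Dme_circ_0009358		0.74476	0.002481	CaMKI
Dme_circ_0000626		3.7656	0.03384	CG17646
Dme_circ_0011075		3.7618	0.03415	Trf2
Dme_circ_0006956		3.5884	0.045804	GluClalpha
Dme_circ_0009667		3.559	0.048096	dlg1
Dme_circ_0009514		4.0161	0.021197	pan
Dme_circ_0006334		3.8925	0.026799	CG42402
Dme_circ_0008173		3.881	0.027405	Nlg1
Dme_circ_0004404		0.61768	0.020721	Dbp80
Dme_circ_0003891	Dme_circ_0001623	-3.8065	0.033572	psq
Dme_circ_0006619	Dme_circ_0003501	-4.3746	0.010954	srp
Dme_circ_0004913	Dme_circ_0004913	-0.52833	0.047568	CG34347
Dme_circ_0004843		-0.48662	0.02228	CG15715
Dme_circ_0010498		-0.73454	0.04614	CG1304
Dme_circ_0006913		-2.7169	0.042802	Cyp12a5
Dme_circ_0010310		-3.8065	0.033572	arm
Dme_circ_0009500		-4.0543	0.021183	pan
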
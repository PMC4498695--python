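proband_id	gene	nucleotide_change	amino_acid_change	state	polyphen	provean	sift	EVS	ExAC	NC	RC	reported
MD19	ABCA4	c.4793C>G	p.A1598G	het	PoD	D	NA	0.0001	NA	-	0/456	known
MD19	ABCA4	c.634C>T	p.R212C	het	NA	D	D	0.0002	14/120056	-	0/456	known
QT058	ABCA4	c.4773+1G>T	Splicing defect	het	SSA	NA	NA	NA	NA	-	0/456	known
QT058	ABCA4	c.6173T>G	p.L2058R	het	PrD	D	D	NA	NA	0/192	0/456	novel
QT085	ABCA4	c.5932delA	p.K1978Qfs*13	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT085	ABCA4	c.6173T>G	p.L2058R	het	PrD	D	D	NA	NA	0/192	0/456	novel
QT1137	ABCA4	c.22C>T	p.Q8*	het	NA	NA	NA	0.0001	NA	0/192	0/456	novel
QT1137	ABCA4	c.6284A>T	p.D2095V	het	PrD	D	D	NA	NA	0/192	0/456	novel
QT1160	ABCA4	c.101_106del	p.S34_L35del	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT1160	ABCA4	c.240_241del	p.C81Ffs*17	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT1175	ABCA4	c.2894A>G	p.N965S	het	PrD	D	D	0.0001	21/121302	-	0/456	known
QT1175	ABCA4	c.4195G>T	p.E1399*	het	NA	NA	NA	NA	2/120596	0/192	0/456	novel
QT1182	ABCA4	c.4773+1G>T	Splicing defect	hom	SSA	NA	NA	NA	NA	-	0/456	known
QT1198	ABCA4	c.2894A>G	p.N965S	het	PrD	D	D	0.0001	21/121302	-	0/456	known
QT1198	ABCA4	c.5646G>A	p.M1882I	het	PoD	D	D	NA	3/121340	-	0/456	known
QT1200	ABCA4	c.6563T>C	p.F2188S	het	B	D	D	0.0005	2/121380	-	1/456	known
QT1200	ABCA4	c.858+2T>A	Splicing defect	het	SSA	NA	NA	NA	NA	-	0/456	known
QT1230	ABCA4	c.101_106del	p.S34_L35del	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT1230	ABCA4	c.6317G>C	p.R2106P	het	PrD	D	D	NA	NA	0/192	0/456	novel
QT1277	ABCA4	c.5196+1G>A	Splicing defect	het	SSA	NA	NA	NA	3/49858	-	0/456	known
QT1277	ABCA4	c.6479+2T>C	Splicing defect	het	SSA	NA	NA	NA	NA	0/192	0/456	novel
QT1317	ABCA4	c.4622T>C	p.L1541P	het	PrD	D	D	NA	NA	0/192	0/456	novel
QT1317	ABCA4	c.5646G>A	p.M1882I	het	PoD	D	D	NA	3/121340	-	0/456	known
QT292	ABCA4	c.6118C>T	p.R2040*	het	NA	NA	NA	NA	2/121394	0/192	0/456	known
QT292	ABCA4	c.6389T>A	p.M2130K	het	PoD	D	D	NA	NA	-	0/456	known
QT302	ABCA4	c.4555delA	p.T1519Rfs*7	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT302	ABCA4	c.6816+1G>A	Splicing defect	het	SSA	NA	NA	NA	NA	-	0/456	known
QT398	ABCA4	c.1804C>T	p.R602W	het	PoD	D	D	NA	6/119038	-	2/456	known
QT398	ABCA4	c.4352+1G>A	Splicing defect	het	SSA	NA	NA	NA	1/121268	-	0/456	known
QT431	ABCA4	c.1804C>T	p.R602W	het	PoD	D	D	NA	6/119038	-	2/456	known
QT431	ABCA4	c.5646G>A	p.M1882I	het	PoD	D	D	NA	3/121340	-	0/456	known
QT458	ABCA4	c.164A>G	p.H55R	het	PoD	D	D	NA	NA	-	0/456	known
QT458	ABCA4	c.4555delA	p.T1519Rfs*7	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT727	ABCA4	c.101_106del	p.S34_L35del	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT727	ABCA4	c.161-2A>G	Splicing defect	het	SSA	NA	NA	NA	NA	0/192	0/456	novel
QT833	ABCA4	c.1560delG	p.V521Sfs*47	het	NA	NA	NA	NA	NA	0/192	0/456	novel
QT833	ABCA4	c.2424C>G	p.Y808*	het	NA	NA	NA	NA	NA	-	0/456	known
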
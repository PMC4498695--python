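variant_id	gene	chrom	pos	ref	alt	cdna_name	protein_name	consequence	splice_flag	polyphen	sift	provean	reported_status	EVS_maf	ExAC_ac	ExAC_an
ABCA4:c.101_106del	ABCA4	1	94599899	NNNNNNN	N	c.101_106del	p.S34_L35del	inframe_indel	False	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.1560delG	ABCA4	1	94598440	NG	N	c.1560delG	p.V521Sfs*47	frameshift	False	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.161-2A>G	ABCA4	1	94599839	A	G	c.161-2A>G	NA	splice_site	True	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.164A>G	ABCA4	1	94599836	A	G	c.164A>G	p.H55R	missense	False	PoD	D	D	known	NA	NA	NA
ABCA4:c.1804C>T	ABCA4	1	94598196	C	T	c.1804C>T	p.R602W	missense	False	PoD	D	D	known	NA	6	119038
ABCA4:c.22C>T	ABCA4	1	94599978	C	T	c.22C>T	p.Q8*	nonsense	False	NA	NA	NA	novel	0.0001	NA	NA
ABCA4:c.240_241del	ABCA4	1	94599760	NNN	N	c.240_241del	p.C81Ffs*17	frameshift	False	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.2424C>G	ABCA4	1	94597576	C	G	c.2424C>G	p.Y808*	nonsense	False	NA	NA	NA	known	NA	NA	NA
ABCA4:c.2894A>G	ABCA4	1	94597106	A	G	c.2894A>G	p.N965S	missense	False	PrD	D	D	known	0.0001	21	121302
ABCA4:c.4195G>T	ABCA4	1	94595805	G	T	c.4195G>T	p.E1399*	nonsense	False	NA	NA	NA	novel	NA	2	120596
ABCA4:c.4352+1G>A	ABCA4	1	94595648	G	A	c.4352+1G>A	NA	splice_site	True	NA	NA	NA	known	NA	1	121268
ABCA4:c.4555delA	ABCA4	1	94595445	NA	N	c.4555delA	p.T1519Rfs*7	frameshift	False	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.4622T>C	ABCA4	1	94595378	T	C	c.4622T>C	p.L1541P	missense	False	PrD	D	D	novel	NA	NA	NA
ABCA4:c.4773+1G>T	ABCA4	1	94595227	G	T	c.4773+1G>T	NA	splice_site	True	NA	NA	NA	known	NA	NA	NA
ABCA4:c.4793C>G	ABCA4	1	94595207	C	G	c.4793C>G	p.A1598G	missense	False	PoD	NA	D	known	0.0001	NA	NA
ABCA4:c.5196+1G>A	ABCA4	1	94594804	G	A	c.5196+1G>A	NA	splice_site	True	NA	NA	NA	known	NA	3	49858
ABCA4:c.5646G>A	ABCA4	1	94594354	G	A	c.5646G>A	p.M1882I	missense	False	PoD	D	D	known	NA	3	121340
ABCA4:c.5932delA	ABCA4	1	94594068	NA	N	c.5932delA	p.K1978Qfs*13	frameshift	False	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.6118C>T	ABCA4	1	94593882	C	T	c.6118C>T	p.R2040*	nonsense	False	NA	NA	NA	known	NA	2	121394
ABCA4:c.6173T>G	ABCA4	1	94593827	T	G	c.6173T>G	p.L2058R	missense	False	PrD	D	D	novel	NA	NA	NA
ABCA4:c.6284A>T	ABCA4	1	94593716	A	T	c.6284A>T	p.D2095V	missense	False	PrD	D	D	novel	NA	NA	NA
ABCA4:c.6317G>C	ABCA4	1	94593683	G	C	c.6317G>C	p.R2106P	missense	False	PrD	D	D	novel	NA	NA	NA
ABCA4:c.634C>T	ABCA4	1	94599366	C	T	c.634C>T	p.R212C	missense	False	NA	D	D	known	0.0002	14	120056
ABCA4:c.6389T>A	ABCA4	1	94593611	T	A	c.6389T>A	p.M2130K	missense	False	PoD	D	D	known	NA	NA	NA
ABCA4:c.6479+2T>C	ABCA4	1	94593521	T	C	c.6479+2T>C	NA	splice_site	True	NA	NA	NA	novel	NA	NA	NA
ABCA4:c.6563T>C	ABCA4	1	94593437	T	C	c.6563T>C	p.F2188S	missense	False	B	D	D	known	0.0005	2	121380
ABCA4:c.6816+1G>A	ABCA4	1	94593184	G	A	c.6816+1G>A	NA	splice_site	True	NA	NA	NA	known	NA	NA	NA
ABCA4:c.858+2T>A	ABCA4	1	94599142	T	A	c.858+2T>A	NA	splice_site	True	NA	NA	NA	known	NA	NA	NA
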
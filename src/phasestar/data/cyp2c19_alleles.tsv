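# Simplified CYP2C19 star-allele definition table (GRCh38, chromosome 10 / NC_000010.11).
# Documented variant-allele relationships are encoded at their published genomic
# positions; positions whose only role is to distinguish suballeles from one
# another are synthetic placeholders and carry an SYN_-prefixed rsid.
#reference_allele=*38.001
gene	suballele	major	function	chrom	pos	ref	alt	rsid	is_core
CYP2C19	*1.001	*1	normal	10	94842866	A	G		1
CYP2C19	*1.002	*1	normal	10	94842866	A	G		1
CYP2C19	*1.002	*1	normal	10	94765001	T	C	SYN_S1002	0
CYP2C19	*1.005	*1	normal	10	94842866	A	G		1
CYP2C19	*1.005	*1	normal	10	94766002	G	A	SYN_S1005	0
CYP2C19	*1.006	*1	normal	10	94842866	A	G		1
CYP2C19	*1.006	*1	normal	10	94767003	C	A	SYN_S1006	0
CYP2C19	*2.001	*2	no_function	10	94781859	G	A		1
CYP2C19	*2.002	*2	no_function	10	94781859	G	A		1
CYP2C19	*2.002	*2	no_function	10	94775165	G	C		0
CYP2C19	*2.002	*2	no_function	10	94768004	A	G	SYN_S2002	0
CYP2C19	*2.010	*2	no_function	10	94781859	G	A		1
CYP2C19	*2.010	*2	no_function	10	94775165	G	C		0
CYP2C19	*2.010	*2	no_function	10	94769005	C	T	SYN_S2010	0
CYP2C19	*2.011	*2	no_function	10	94781859	G	A		1
CYP2C19	*2.011	*2	no_function	10	94762608	T	C	rs4986894	0
CYP2C19	*2.012	*2	no_function	10	94781859	G	A		1
CYP2C19	*2.012	*2	no_function	10	94775165	G	C		0
CYP2C19	*2.012	*2	no_function	10	94771006	G	T	SYN_S2012	0
CYP2C19	*3.002	*3	no_function	10	94780653	G	A	SYN_S3CORE	1
CYP2C19	*3.002	*3	no_function	10	94781616	A	G	rs7088784	0
CYP2C19	*11.001	*11	normal	10	94775507	G	A		1
CYP2C19	*17.001	*17	increased	10	94761001	C	T	SYN_S17UP	1
CYP2C19	*38.001	*38	normal						
CYP2C19	*38.003	*38	normal	10	94770005	T	G	SYN_S38003	0
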
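# Published 37-sample CYP2C19 diplotype calls: manual curation vs three
# star-allele tools.  Cells are verbatim call strings including "+extra"
# annotations and, for PharmCat, the bracketed alternative listed when the
# manually curated diplotype appeared in the output list but not first.
# Sample 5's manual cell uses an unexplained "-variant" notation which is
# preserved as printed.
sample	manual	aldy	pharmaku	pharmcat
1	*1.002/*38.003 + 94781616A>G (NM)	*1.001 + rs17885098/*1.005 (NM)	*1/*1 (NM)	*1/*5
2	*1.002/*38.003 + 94781616A>G (NM)	*1.001 + rs17885098/*1.005 (NM)	*1/*1 (NM)	*1/*5
3	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
4	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
5	*1.002 +94842865C>T/*2.002-94842865C>T (IM)	*1.002/*2.002 (IM)	*1/*2 (IM)	*1/*2
6	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
7	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
8	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
9	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
10	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
11	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
12	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
13	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
14	*1.002/*1.006 (NM)	*1.002/*1.006 (NM)	*1/*1 (NM)	*1/*1
15	*17.001/*38.003 + 94781616A>G (RM)	*1.001/*17.001 (RM)	*1/*17 (RM)	*4/*38 (*17/*38)
16	*1.002/*2.011 + 94775507G>A (IM)	*2.001/*11.001 + rs4986894 (IM)	*1/*2 (IM)	*1/*2
17	*1.002/*2.012 (IM)	*1.002/*2.002 (IM)	*1/*2 (IM)	*1/*2
18	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
19	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
20	*1.002/*38.003 + 94781616A>G (NM)	*1.001 + rs17885098/*1.005 (NM)	*1/*1 (NM)	*1/*5
21	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
22	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
23	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
24	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
25	*1.002/*2.011 (IM)	*1.002 + rs4986894/*2.001 (IM)	*1/*2 (IM)	*1/*2
26	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
27	*1.002/*2.011 (IM)	*1.002 + rs4986894/*2.001 (IM)	*1/*2 (IM)	*1/*2
28	*1.002/*17.001 (RM)	*1.002/*17.001 (RM)	*1/*17 (RM)	*1/*4 (*1/*17)
29	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
30	*1.002/*2.011 (IM)	*1.002 + rs4986894/*2.001 (IM)	*1/*2 (IM)	*1/*2
31	*1.002/*2.011 (IM)	*1.002 + rs4986894/*2.001 (IM)	*1/*2 (IM)	*1/*2
32	*1.002/*2.011 (IM)	*1.002 + rs4986894/*2.001 (IM)	*1/*2 (IM)	*1/*2
33	*1.002/*1.002 (NM)	*1.002/*1.002 (NM)	*1/*1 (NM)	*1/*1
34	*1.002/*2.011 (IM)	*1.002 + rs4986894/*2.001 (IM)	*1/*2 (IM)	*1/*2
35	*1.002/*38.003 + 94781616A>G (NM)	*1.001 + rs17885098/*1.005 (NM)	*1/*1 (NM)	*1/*5
36	*2.011/*17.001 (IM)	*2.001/*17.001 + rs4986894 (IM)	*2/*17 (IM)	*2/*4 (*2/*17)
37	*1.002/*38.003 + 94781616A>G (NM)	*1.001 + rs17885098/*1.005 (NM)	*1/*1 (NM)	*1/*5
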
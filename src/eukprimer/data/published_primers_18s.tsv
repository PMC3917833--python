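# Published universal eukaryote 18S rRNA primers. Ids give the 1-based
# position of the primer's 5' terminus on the S. cerevisiae 18S rRNA gene.
# published_tm_c and published_gc_percent are the values reported alongside
# the primers (vendor-tool melting temperatures), kept here as reference
# inputs for cross-checking computed physical properties.
id	sequence	orientation	published_tm_c	published_gc_percent
F-555	AAGTCTGGTGCCAGCAGCCG	forward	63	65
F-565	CCAGCAGCCGCGGTAATTCC	forward	61.5	65
F-566	CAGCAGCCGCGGTAATTCC	forward	59.4	63.2
F-573	CGCGGTAATTCCAGCTCCA	forward	60	57.9
F-574	GCGGTAATTCCAGCTCCAA	forward	55.3	52.6
F-1183	AATTTGACTCAACACGGG	forward	52	44.4
F-1422	ATAACAGGTCTGTGATGC	forward	49.2	44.4
F-1624	CCTTTGTACACACCGCCCGTCG	forward	62.7	63.6
R-574	CGGCTGCTGGCACCAGACTTGC	reverse	65.7	68.2
R-1196	TGTTGAGTCAAATTAAGC	reverse	44.8	33.3
R-1200	CCCGTGTTGAGTCAAATTAAGC	reverse	54.4	45.5
R-1289	ACTAAGAACGGCCATGCACC	reverse	57.9	55
R-1438	CATCACAGACCTGTTATTGC	reverse	51.3	45
R-1631	TACAAAGGGCAGGGACG	reverse	54.6	58.8
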
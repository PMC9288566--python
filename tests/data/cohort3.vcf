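##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=10000>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	plantA	plantB	plantC
chr1	100	.	A	G	120	.	.	GT	0/1	0/0	0/0
chr1	200	.	C	T	150	.	.	GT	0/0	0/1	0/0
chr1	300	.	G	A	90	.	.	GT	0/1	0/1	0/0
chr1	400	.	G	A	200	.	.	GT	1/1	0/0	0/0
chr1	500	.	T	C	75	.	.	GT	0/1	0/0	0/0
chr1	700	.	G	T	99	.	.	GT	0/0	0/0	0/1
chr1	800	.	GA	G	130	.	.	GT	0/1	0/0	0/0
chr1	900	.	C	CTT	140	.	.	GT	0/0	0/1	0/0
chr1	950	.	G	A	101	.	.	GT	0/1	0/1	0/1
chr1	1000	.	T	A	85	.	.	GT	0/1	./.	0/0
chr1	5500	.	AT	A	180	.	.	GT	0/0	0/1	0/0
chr1	5600	.	C	T	160	.	.	GT	0/0	0/0	0/1
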
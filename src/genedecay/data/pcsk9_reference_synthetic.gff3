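##gff-version 3
PCSK9_locus	genedecay	gene	801	6869	.	+	.	ID=PCSK9
PCSK9_locus	genedecay	exon	801	939	.	+	.	ID=PCSK9.exon1;Parent=PCSK9
PCSK9_locus	genedecay	CDS	801	939	.	+	0	ID=PCSK9.cds1;Parent=PCSK9
PCSK9_locus	genedecay	exon	1360	1545	.	+	.	ID=PCSK9.exon2;Parent=PCSK9
PCSK9_locus	genedecay	CDS	1360	1545	.	+	0	ID=PCSK9.cds2;Parent=PCSK9
PCSK9_locus	genedecay	exon	1856	1969	.	+	.	ID=PCSK9.exon3;Parent=PCSK9
PCSK9_locus	genedecay	CDS	1856	1969	.	+	0	ID=PCSK9.cds3;Parent=PCSK9
PCSK9_locus	genedecay	exon	2335	2487	.	+	.	ID=PCSK9.exon4;Parent=PCSK9
PCSK9_locus	genedecay	CDS	2335	2487	.	+	0	ID=PCSK9.cds4;Parent=PCSK9
PCSK9_locus	genedecay	exon	2768	2860	.	+	.	ID=PCSK9.exon5;Parent=PCSK9
PCSK9_locus	genedecay	CDS	2768	2860	.	+	0	ID=PCSK9.cds5;Parent=PCSK9
PCSK9_locus	genedecay	exon	3191	3325	.	+	.	ID=PCSK9.exon6;Parent=PCSK9
PCSK9_locus	genedecay	CDS	3191	3325	.	+	0	ID=PCSK9.cds6;Parent=PCSK9
PCSK9_locus	genedecay	exon	3736	3885	.	+	.	ID=PCSK9.exon7;Parent=PCSK9
PCSK9_locus	genedecay	CDS	3736	3885	.	+	0	ID=PCSK9.cds7;Parent=PCSK9
PCSK9_locus	genedecay	exon	4181	4366	.	+	.	ID=PCSK9.exon8;Parent=PCSK9
PCSK9_locus	genedecay	CDS	4181	4366	.	+	0	ID=PCSK9.cds8;Parent=PCSK9
PCSK9_locus	genedecay	exon	4717	4890	.	+	.	ID=PCSK9.exon9;Parent=PCSK9
PCSK9_locus	genedecay	CDS	4717	4890	.	+	0	ID=PCSK9.cds9;Parent=PCSK9
PCSK9_locus	genedecay	exon	5196	5315	.	+	.	ID=PCSK9.exon10;Parent=PCSK9
PCSK9_locus	genedecay	CDS	5196	5315	.	+	0	ID=PCSK9.cds10;Parent=PCSK9
PCSK9_locus	genedecay	exon	5701	6144	.	+	.	ID=PCSK9.exon11;Parent=PCSK9
PCSK9_locus	genedecay	CDS	5701	6144	.	+	0	ID=PCSK9.cds11;Parent=PCSK9
PCSK9_locus	genedecay	exon	6485	6869	.	+	.	ID=PCSK9.exon12;Parent=PCSK9
PCSK9_locus	genedecay	CDS	6485	6669	.	+	0	ID=PCSK9.cds12;Parent=PCSK9
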
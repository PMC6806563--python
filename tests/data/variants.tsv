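VariationID	Type	Name	ClinicalSignificance	Assembly	Chromosome	Start	ReferenceAlleleVCF	AlternateAlleleVCF	GeneSymbol	PhenotypeIDS
1	single nucleotide variant	NM_000001.1(GENE1):c.251G>A	Pathogenic	GRCh38	chr1	251	G	A	GENE1	MONDO:0000001
2	single nucleotide variant	NM_000002.1(GENE1):c.351C>T	Pathogenic	GRCh38	chr1	351	C	T	GENE1	MONDO:0000001
3	single nucleotide variant	NM_000003.1(GENE1):c.1261C>T	Pathogenic	GRCh38	chr1	1261	C	T	GENE1	MONDO:0000001
4	single nucleotide variant	NM_000004.1(GENE1):c.424C>T	Pathogenic	GRCh38	chr1	424	C	T	GENE1	MONDO:0000001
5	single nucleotide variant	NM_000005.1(GENE1):c.451A>G	Pathogenic	GRCh38	chr1	451	A	G	GENE1	MONDO:0000001
6	single nucleotide variant	NM_000006.1(GENE1):c.806A>G	Pathogenic	GRCh38	chr1	806	A	G	GENE1	MONDO:0000001
7	single nucleotide variant	NM_000007.1(GENE1):c.147A>G	Pathogenic	GRCh38	chr1	147	A	G	GENE1	MONDO:0000001
8	single nucleotide variant	NM_000008.1(GENE1):c.1031T>C	Pathogenic	GRCh38	chr1	1031	T	C	GENE1	MONDO:0000001
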
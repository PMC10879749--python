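hgnc_id	ensembl_gene_id	gene_symbol
HGNC:5031	ENSG00000135486	HNRNPA1
HGNC:4851	ENSG00000197386	HTT
HGNC:3775	ENSG00000102081	FMR1
HGNC:2933	ENSG00000104936	DMPK
HGNC:10548	ENSG00000124788	ATXN1
HGNC:28337	ENSG00000147894	C9orf72
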
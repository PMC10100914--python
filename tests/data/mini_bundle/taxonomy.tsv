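taxon_id	domain	marker	lineage
b1	bacteria	16S	Bacteria;Desulfobacterota;SEEP-SRB1
b2	archaea	16S	Archaea;Halobacterota;ANME-1b
f1	fungus	18S	Eukaryota;Fungi;Ascomycota;Fusarium
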
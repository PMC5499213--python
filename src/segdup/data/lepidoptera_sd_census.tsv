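# Published segmental-duplication census for five lepidopteran genomes
# (counts as printed in the source census; bins: >=90, 80-90, 75-80 percent identity)
species	total_sds	n_ge90	n_80_90	n_75_80	total_mb	pct_genome	n_genes	pct_genes
P_xylostella	21369	18064	3204	997	43	11	2235	12.4
M_sexta	11141	8892	2171	81	19.1	5.2	1040	6.8
H_melpomene	23942	21572	2239	127	40.5	15.2	1453	11
D_plexippus	10799	10070	668	60	23.5	9.9	1564	10.3
B_mori	3667	3221	416	5	5.6	1.2	332	2.3
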
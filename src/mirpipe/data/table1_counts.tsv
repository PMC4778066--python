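category	unique_ctl	total_ctl	unique_def	total_def
clean_reads	4024507	20328011	4680037	22218850
mapped_to_genome	2057122	10424352	2498165	14966029
exon_antisense	43345	168476	36748	185172
exon_sense	73814	297258	78538	383020
intron_antisense	39066	241915	46841	320641
intron_sense	55378	433107	65216	716855
miRNA	42935	2280530	49819	4888886
rRNA	270955	7699010	157928	3063831
repeat	832	2139	1126	3516
snRNA	4548	15986	2727	7986
snoRNA	1228	2466	1011	2351
tRNA	19314	347898	20326	832644
unannotated	3473092	8839226	4219757	11813948
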
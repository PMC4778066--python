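mirna_id	mirna_log2fc	target_id	target_name	relative_change
miR164	-2.38730699	orange1.1g030909m	NAC domain containing protein 1	1.4372
miR164	-2.38730699	orange1.1g047710m	NAC domain transcriptional regulator superfamily protein	0.6610
miR164	-2.38730699	orange1.1g017827m	NAC domain containing protein 100	2.9265
miR158	-6.05735341	orange1.1g001709m	Lipase class 3 family protein	4.1384
miR158	-6.05735341	orange1.1g002569m	Disease resistance protein (CC-NBS-LRR class) family	3.2507
miR158	-6.05735341	orange1.1g038105m	Disease resistance protein (CC-NBS-LRR class) family	1.6141
miR158	-6.05735341	orange1.1g041843m	LRR and NB-ARC domains-containing disease resistance protein	0.7305
miR833	5.7705023	orange1.1g047519m	Receptor like protein 6	0.5503
miR1507	1.99337925	orange1.1g034576m	NB-ARC domain-containing disease resistance protein	0.1031
miR1507	1.99337925	orange1.1g042037m	LRR and NB-ARC domains-containing disease resistance protein	0.5256
miR1507	1.99337925	orange1.1g045522m	HOPZ-ACTIVATED RESISTANCE 1	1.6070
miR156	-1.91583036	orange1.1g016971m	Squamosa promoter-binding protein-like transcription factor	ND
miR156	-1.91583036	orange1.1g021420m	Squamosa promoter-binding protein-like transcription factor	1.3295
miR156	-1.91583036	orange1.1g008680m	Squamosa promoter-binding protein-like transcription factor	2.0745
miR156	-1.91583036	orange1.1g009653m	Squamosa promoter-binding protein-like transcription factor	1.5065
miR156	-1.91583036	orange1.1g011640m	Squamosa promoter binding protein-like 2	1.4202
miR156	-1.91583036	orange1.1g011651m	Squamosa promoter binding protein-like 2	ND
miR156	-1.91583036	orange1.1g032310m	Squamosa promoter binding protein-like 3	3.4314
miR156	-1.91583036	orange1.1g029650m	Squamosa promoter binding protein-like 4	2.0105
miR156	-1.91583036	orange1.1g032937m	Squamosa promoter binding protein-like 5	0.8213
miR156	-1.91583036	orange1.1g046416m	Squamosa promoter binding protein-like 9	3.8189
miR156	-1.91583036	orange1.1g030599m	Squamosa promoter-binding protein-like 12	1.1053
miR7812	-7.07931495	orange1.1g017621m	Leucine-rich repeat receptor-like protein kinase family protein	0.7175
miR7812	-7.07931495	orange1.1g038769m	Aldehyde dehydrogenase 2C4	3.2200
miR5821	10.86451118	orange1.1g045278m	NAC 014	0.4220
miR5821	10.86451118	orange1.1g022991m	Senescence associated gene 18	1.3523
miR5821	10.86451118	orange1.1g013216m	Peptidase M20/M25/M40 family protein	0.4598
miR5821	10.86451118	orange1.1g013368m	Peptidase M20/M25/M40 family protein	0.9147
miR5821	10.86451118	orange1.1g046783m	Cation efflux family protein	0.5710
miR395	10.30345436	orange1.1g005583m	K+ uptake transporter 3	0.9674
miR395	10.30345436	orange1.1g014749m	SecY protein transport family protein	1.5667
miR395	10.30345436	AT3G22890	APS1	1.5017
miR395	10.30345436	AT4G14680	APS3	ND
miR395	10.30345436	AT5G43780	APS4	0.8727
miR395	10.30345436	AT5G1018	SULTR2;1	0.7439
miR1077	11.84568538	orange1.1g014749m	SecY protein transport family protein	1.7085
miR946	10.29281625	orange1.1g005467m	Transporter associated with antigen processing protein 1	0.4222
miR1160	5.35880943	orange1.1g005451m	Mitochondrial substrate carrier family protein	0.8227
miR1160	5.35880943	orange1.1g004285m	Phosphate 1	1.1364
miR8019	6.3871206	orange1.1g010016m	Proton pump interactor 1	2.5270
miR6218	3.83981303	orange1.1g005203m	Transporter associated with antigen processing protein 1	0.7108
miR6218	3.83981303	orange1.1g003633m	Glutamate receptor 5	0.8682
miR1533	4.30631516	orange1.1g007444m	ALBINA 1	0.6732
miR6426	4.30631516	orange1.1g037454m	Laccase 17	0.8741
miR6426	4.30631516	orange1.1g010327m	Sigma factor E	0.8483
miR3946	-2.16322268	orange1.1g017665m	NAC domain containing protein 47	0.8570
miR3946	-2.16322268	orange1.1g013752m	Basic helix-loop-helix DNA-binding superfamily protein	9.9306
miR3946	-2.16322268	orange1.1g014958m	Basic helix-loop-helix DNA-binding superfamily protein	0.6579
miR3946	-2.16322268	orange1.1g005518m	BEL1-like homeodomain 1	1.2743
miR3946	-2.16322268	orange1.1g025914m	Integrase-type DNA-binding superfamily protein	1.8616
miR3946	-2.16322268	orange1.1g024507m	RNA binding (RRM/RBD/RNP motifs) family protein	1.1601
miR3946	-2.16322268	orange1.1g025497m	General regulatory factor 8	3.6019
miR3946	-2.16322268	orange1.1g011991m	Integrin-linked protein kinase family	6.0692
miR3946	-2.16322268	orange1.1g006091m	Glycogen/starch synthases, ADP-glucose type	0.6423
miR3946	-2.16322268	orange1.1g009139m	Glycogen/starch synthases, ADP-glucose type	1.4300
miR3946	-2.16322268	orange1.1g010449m	Pyruvate kinase family protein	0.7370
miR3946	-2.16322268	orange1.1g002698m	Phosphoenolpyruvate carboxylase 2	2.1231
miR3946	-2.16322268	orange1.1g007773m	Phosphatidylinositol 3- and 4-kinase; Ubiquitin family protein	1.2461
miR3946	-2.16322268	orange1.1g002776m	PLAT/LH2 domain-containing lipoxygenase family protein	ND
miR3946	-2.16322268	orange1.1g016142m	Bidirectional amino acid transporter 1	5.4132
miR3946	-2.16322268	orange1.1g030941m	Translationally controlled tumor protein	0.7158
miR535	-1.56870368	orange1.1g009840m	Cytochrome P450 family 714 subfamily A polypeptide 1	1.8899
miR5256	-3.19897021	orange1.1g004233m	Phospholipase D delta	2.3193
miR5742	-2.88770785	orange1.1g009718m	TCP-1/cpn60 chaperonin family protein	1.9777
miR5742	-2.88770785	orange1.1g041155m	Disease resistance family protein/LRR family protein	1.6675
miR5561	-7.70753451	orange1.1g018677m	G-box binding factor 1	2.5652
miR5561	-7.70753451	orange1.1g019071m	G-box binding factor 1	1.7283
miR5158	-5.92521928	orange1.1g043878m	Protein with RING/U-box and TRAF-like domains	1.9307
miR5158	-5.92521928	orange1.1g042649m	Basic helix-loop-helix DNA-binding superfamily protein	2.7431
miR5818	-4.95063483	orange1.1g001860m	NB-ARC domain-containing disease resistance protein	3.9827
miR779	-8.10749886	orange1.1g027903m	Cyclin p1;1	3.9679
miR779	-8.10749886	orange1.1g044779m	Ammonium transporter 2	7.1508
miR779	-8.10749886	orange1.1g041074m	Ammonium transporter 2	7.9240
miR779	-8.10749886	orange1.1g042791m	NB-ARC domain-containing disease resistance protein	2.2157
miR779	-8.10749886	orange1.1g001921m	RNA binding (RRM/RBD/RNP motifs) family protein	9.5707
miR779	-8.10749886	orange1.1g025347m	Expansin A8	21.0361
miR779	-8.10749886	orange1.1g045028m	Protein tyrosine kinase family protein	0.7103
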
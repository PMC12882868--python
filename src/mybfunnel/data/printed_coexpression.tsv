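query_name	query_accession	partner_accession	annotation	category	note	r
SvMYB24	Sevir.2G296900	Sevir.5G268700	NAC DOMAIN CONTAINING PROTEIN 73	lignin_related	Related to AtSND2/AtNAC73	0.973
SvMYB24	Sevir.2G296900	Sevir.J014600	Flavonoid 3'-monooxygenase/flavonoid 3'-hydroxylase	phenylpropanoid_related		0.958
SvMYB24	Sevir.2G296900	Sevir.9G244500	Flavonoid 3'-monooxygenase/flavonoid 3'-hydroxylase	phenylpropanoid_related		0.954
SvMYB24	Sevir.2G296900	Sevir.5G371400	Laccase	lignin_related	Related to AtLAC5 and AtLAC12	0.935
SvMYB24	Sevir.2G296900	Sevir.2G228900	Flavonoid 3'-monooxygenase/flavonoid 3'-hydroxylase	phenylpropanoid_related		0.925
SvMYB24	Sevir.2G296900	Sevir.4G252600	NAC DOMAIN CONTAINING PROTEIN 75-related	lignin_related	Related to AtSND4/AtNAC75	0.911
SvMYB24	Sevir.2G296900	Sevir.5G382900	Laccase	lignin_related	Related to AtLAC17	0.907
SvMYB24	Sevir.2G296900	Sevir.8G224900	Laccase	lignin_related		0.894
SvMYB24	Sevir.2G296900	Sevir.8G221900	Laccase	lignin_related		0.893
SvMYB24	Sevir.2G296900	Sevir.6G231400	Class III peroxidase	lignin_related		0.890
SvMYB24	Sevir.2G296900	Sevir.5G216900	Hydroxycinnamaldehyde dehydrogenase (ALDH2C/REF1)	lignin_related	Related to HCALDH	0.888
SvMYB24	Sevir.2G296900	Sevir.7G269000	Shikimate kinase	phenylpropanoid_related		0.887
SvMYB24	Sevir.2G296900	Sevir.6G187100	Phenylalanine/tyrosine ammonia-lyase (PTAL)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.886
SvMYB24	Sevir.2G296900	Sevir.4G195000	Class III peroxidase	lignin_related		0.885
SvMYB24	Sevir.2G296900	Sevir.5G383000	Laccase	lignin_related	Related to AtLAC17	0.883
SvMYB24	Sevir.2G296900	Sevir.9G228100	Feruloyl esterase/hydroxycinnamoyl esterase	phenylpropanoid_related		0.882
SvMYB24	Sevir.2G296900	Sevir.3G277100	Class III peroxidase	lignin_related		0.881
SvMYB24	Sevir.2G296900	Sevir.8G262800	Laccase	lignin_related	Related to AtLAC4	0.879
SvMYB24	Sevir.2G296900	Sevir.7G178200	Phenylalanine/tyrosine ammonia-lyase (PTAL)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.875
SvMYB24	Sevir.2G296900	Sevir.4G044900	Hydroxycinnamoyl CoA:shikimate hydroxycinnamoyl transferase (HCT)	lignin_biosynthesis		0.873
SvMYB24	Sevir.2G296900	Sevir.2G339400	Laccase	lignin_related		0.864
SvMYB24	Sevir.2G296900	Sevir.1G056800	Cinnamyl alcohol dehydrogenase (CAD)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.862
SvMYB24	Sevir.2G296900	Sevir.9G395800	Flavonoid 3',5'-hydroxylase (CYP75A)	phenylpropanoid_related		0.860
SvMYB24	Sevir.2G296900	Sevir.5G383300	Laccase	lignin_related	Related to AtLAC17	0.859
SvMYB24	Sevir.2G296900	Sevir.3G412600	(+)-pinoresinol reductase/lariciresinol reductase	lignin_related		0.857
SvMYB24	Sevir.2G296900	Sevir.8G016500	Laccase	lignin_related	Related to AtLAC5 and AtLAC12	0.853
SvMYB74	Sevir.5G277100	Sevir.6G187100	Phenylalanine/tyrosine ammonia-lyase (PTAL)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.945
SvMYB74	Sevir.5G277100	Sevir.9G395800	Flavonoid 3',5'-hydroxylase (CYP75A)	phenylpropanoid_related		0.945
SvMYB74	Sevir.5G277100	Sevir.5G216900	Hydroxycinnamaldehyde dehydrogenase (ALDH2C/REF1)	lignin_related	Related to HCALDH	0.931
SvMYB74	Sevir.5G277100	Sevir.8G222400	Laccase	lignin_related		0.922
SvMYB74	Sevir.5G277100	Sevir.5G383300	Laccase	lignin_related	Related to AtLAC17	0.920
SvMYB74	Sevir.5G277100	Sevir.1G245100	Phenylalanine ammonia-lyase (PAL)	lignin_biosynthesis		0.917
SvMYB74	Sevir.5G277100	Sevir.6G231400	Class III peroxidase	lignin_related		0.914
SvMYB74	Sevir.5G277100	Sevir.7G178200	Phenylalanine/tyrosine ammonia-lyase (PTAL)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.913
SvMYB74	Sevir.5G277100	Sevir.8G221600	Laccase	lignin_related		0.906
SvMYB74	Sevir.5G277100	Sevir.2G143400	Flavone/flavonol 7-O-beta-d-glucoside malonyltransferase	phenylpropanoid_related		0.903
SvMYB74	Sevir.5G277100	Sevir.7G337400	Class III peroxidase	lignin_related	Lignin-related in S. viridis	0.903
SvMYB74	Sevir.5G277100	Sevir.4G044900	Hydroxycinnamoyl CoA:shikimate hydroxycinnamoyl transferase (HCT)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.902
SvMYB74	Sevir.5G277100	Sevir.5G268700	NAC DOMAIN CONTAINING PROTEIN 73	lignin_related	Related to AtSND2/AtNAC73	0.902
SvMYB74	Sevir.5G277100	Sevir.2G003200	Laccase	lignin_related		0.900
SvMYB74	Sevir.5G277100	Sevir.8G262800	Laccase	lignin_related	Related to AtLAC4	0.896
SvMYB74	Sevir.5G277100	Sevir.4G201300	4-Coumarate:CoA ligase (4CL)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.892
SvMYB74	Sevir.5G277100	Sevir.3G223200	Laccase	lignin_related	Related to AtLAC17	0.885
SvMYB74	Sevir.5G277100	Sevir.6G244700	MYB42/85	lignin_related	Related to AtMYB42/85	0.884
SvMYB74	Sevir.5G277100	Sevir.4G195000	Class III peroxidase	lignin_related		0.881
SvMYB74	Sevir.5G277100	Sevir.8G013900	Class III peroxidase	lignin_related		0.880
SvMYB74	Sevir.5G277100	Sevir.1G245000	Phenylalanine/tyrosine ammonia-lyase (PTAL)	lignin_biosynthesis	Part of the lignin toolbox in S. viridis	0.879
SvMYB74	Sevir.5G277100	Sevir.9G368000	Flavonoid 3'-monooxygenase/flavonoid 3'-hydroxylase	phenylpropanoid_related		0.877
SvMYB74	Sevir.5G277100	Sevir.3G277100	Class III peroxidase	lignin_related		0.872
SvMYB74	Sevir.5G277100	Sevir.8G223000	Laccase	lignin_related		0.871
SvMYB74	Sevir.5G277100	Sevir.1G016500	Benzyl alcohol O-benzoyltransferase	phenylpropanoid_related		0.870
SvMYB74	Sevir.5G277100	Sevir.J014600	Flavonoid 3'-monooxygenase/flavonoid 3'-hydroxylase	phenylpropanoid_related		0.867
SvMYB74	Sevir.5G277100	Sevir.2G296900	MYB42/85	lignin_related	Related to AtMYB42/85	0.865
SvMYB74	Sevir.5G277100	Sevir.5G093900	O-succinylbenzoate synthase	phenylpropanoid_related		0.864
SvMYB74	Sevir.5G277100	Sevir.4G287600	Benzyl alcohol O-benzoyltransferase	phenylpropanoid_related		0.864
SvMYB74	Sevir.5G277100	Sevir.6G093500	4-Coumarate:CoA ligase (4CL)	lignin_biosynthesis		0.858
SvMYB74	Sevir.5G277100	Sevir.9G244500	Flavonoid 3'-monooxygenase/flavonoid 3'-hydroxylase	phenylpropanoid_related		0.858
SvMYB74	Sevir.5G277100	Sevir.8G221000	Laccase	lignin_related		0.857
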
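phylotype_id	best_match_name	identity_pct	table2
Akkermansia muciniphila	Akkermansia muciniphila	99	32.9987
Bacteroides cellulosilyticus	Bacteroides cellulosilyticus	99	1.00376
Bacteroides fragilis	Bacteroides fragilis	99	2.88582
Bacteroides stercorirosoris	Bacteroides stercorirosoris	99	1.12923
Bacteroides stercoris	Bacteroides stercoris	99	1.50565
Bacteroides uniformis	Bacteroides uniformis	99	2.76035
Bacteroides vulgatus	Bacteroides vulgatus	99	2.50941
Bacteroides xylanisolvens	Bacteroides xylanisolvens	99	5.64617
Blautia faecis	Blautia faecis	96.5	1.38018
Blautia glucerasea	Blautia glucerasea	99	4.51694
Coprococcus eutactus	Coprococcus eutactus	99	2.00753
Faecalibacterium prausnitzii	Faecalibacterium prausnitzii	99	12.2961
Muribaculum intestinale	Muribaculum intestinale	99	12.798
Murimonas intestini	Murimonas intestini	92	3.76412
Parabacteroides distasonis	Parabacteroides distasonis	99	3.88959
Parabacteroides goldsteinii	Parabacteroides goldsteinii	99	1.00376
Phascolarctobacterium faecium	Phascolarctobacterium faecium	96.5	3.13676
Ruminococcus champanellensis	Ruminococcus champanellensis	99	1.00376
Sutterella massiliensis	Sutterella massiliensis	96.5	2.00753
[Eubacterium] rectale	[Eubacterium] rectale	99	1.75659
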
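phylotype_id	best_match_name	identity_pct	table3
Agathobaculum desmolans	Agathobaculum desmolans	99	1.33333
Akkermansia muciniphila	Akkermansia muciniphila	99	1.33333
Bacteroides caccae	Bacteroides caccae	99	3.44444
Bacteroides faecis	Bacteroides faecis	99	5
Bacteroides massiliensis	Bacteroides massiliensis	99	1.88889
Bacteroides ovatus	Bacteroides ovatus	99	1.11111
Bacteroides thetaiotaomicron	Bacteroides thetaiotaomicron	99	28.3333
Bacteroides uniformis	Bacteroides uniformis	99	1.88889
Bacteroides vulgatus	Bacteroides vulgatus	99	3.44444
Clostridium perfringens	Clostridium perfringens	99	2.77778
Eggerthella lenta	Eggerthella lenta	99	0.666667
Escherichia fergusonii	Escherichia fergusonii	99	23.3333
Finegoldia magna	Finegoldia magna	99	5.55556
Flavonifractor plautii	Flavonifractor plautii	99	7.66667
Flintibacter butyricus	Flintibacter butyricus	99	0.222222
Parabacteroides merdae	Parabacteroides merdae	99	1
Peptoniphilus grossensis	Peptoniphilus grossensis	99	7.44444
Phascolarctobacterium faecium	Phascolarctobacterium faecium	96.5	2
Pseudoflavonifractor capillosus	Pseudoflavonifractor capillosus	99	0.222222
Pseudoflavonifractor phocaeensis	Pseudoflavonifractor phocaeensis	96.5	1.33333
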